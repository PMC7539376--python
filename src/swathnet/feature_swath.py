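"""Feature swath extraction: equal-width m/z windows → per-scan intensity rows.

The m/z axis is tiled with contiguous equal-width windows; within each scan,
all peak intensities falling in the same window are summed, giving one
fixed-length feature vector per scan (an *intensity matrix*, scans × windows).
Each row is then normalized by its own maximum so that per-scan and per-run
intensity scale cancels. Window specs may be given either as a plain count or
in the "N×N" display convention, which denotes N² one-dimensional m/z bins
(the square arrangement only matters for heat-map rendering).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import SpectraRun

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "IntensityMatrix",
    "parse_window_spec",
    "build_window_grid",
    "infer_mz_range",
    "extract_feature_swath",
    "concat_matrices",
    "normalize_rows",
    "make_label_vector",
]

_SPEC_RE = re.compile(r"^\s*(\d+)\s*[x×*]\s*(\d+)\s*$")


@dataclass(frozen=True)
class WindowGrid:
    """Contiguous equal-width m/z windows [lo, hi), last window closed."""

    mz_min: float
    mz_max: float
    n_windows: int

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError(f"need mz_min < mz_max, got [{self.mz_min}, {self.mz_max}]")
        if self.n_windows < 1:
            raise ValueError(f"n_windows must be >= 1, got {self.n_windows}")

    @property
    def window_width(self) -> float:
        return (self.mz_max - self.mz_min) / self.n_windows

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.mz_min, self.mz_max, self.n_windows + 1)

    def window_ids(self) -> list[str]:
        e = self.edges
        return [f"mz_{e[j]:.4f}_{e[j + 1]:.4f}" for j in range(self.n_windows)]

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """Window index per m/z value; -1 for out-of-range peaks.

        Interior boundaries are half-open (a peak exactly on an edge belongs
        to the window starting there); mz == mz_max lands in the last window.
        """
        mz = np.asarray(mz, dtype=np.float64)
        idx = np.searchsorted(self.edges, mz, side="right") - 1
        idx[mz == self.mz_max] = self.n_windows - 1
        out = (mz < self.mz_min) | (mz > self.mz_max)
        idx[out] = -1
        return idx


@dataclass
class IntensityMatrix:
    """Scans × windows intensity grid with row identities.

    ``row_ids[i] = (run_id, scan_index)``. ``normalized`` marks whether rows
    have been divided by their maxima (every nonzero row max exactly 1).
    """

    values: np.ndarray
    row_ids: list[tuple[str, int]]
    grid: WindowGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length mismatch")
        if self.values.shape[1] != self.grid.n_windows:
            raise ValueError("column count does not match grid.n_windows")
        if np.any(self.values < 0):
            raise ValueError("negative intensities in matrix")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def parse_window_spec(size_spec: str | int) -> int:
    """'N×N' (or 'NxN'/'N*N') → N² windows; a plain integer → that many."""
    if isinstance(size_spec, (int, np.integer)):
        n = int(size_spec)
    else:
        m = _SPEC_RE.match(str(size_spec))
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            if a != b:
                raise ValueError(f"window spec {size_spec!r}: expected square 'N×N'")
            n = a * b
        else:
            try:
                n = int(str(size_spec).strip())
            except ValueError:
                raise ValueError(f"unparseable window spec {size_spec!r}") from None
    if n < 1:
        raise ValueError(f"window count must be positive, got {n}")
    return n


def build_window_grid(mz_min: float, mz_max: float, size_spec: str | int) -> WindowGrid:
    """Build the equal-width grid covering [mz_min, mz_max]."""
    return WindowGrid(mz_min=float(mz_min), mz_max=float(mz_max),
                      n_windows=parse_window_spec(size_spec))


def infer_mz_range(runs: list[SpectraRun]) -> tuple[float, float]:
    """(floor(global min m/z), ceil(global max m/z)) over all runs' peaks.

    A degenerate range (all peaks at one integer m/z) is widened by 1 Th so a
    valid grid always exists. Errors if every scan is empty.
    """
    lo = math.inf
    hi = -math.inf
    for run in runs:
        for scan in run.scans:
            if scan.n_peaks:
                lo = min(lo, float(scan.mz[0]))
                hi = max(hi, float(scan.mz[-1]))
    if not math.isfinite(lo):
        raise ValueError("cannot infer m/z range: all scans are empty")
    lo_i, hi_i = math.floor(lo), math.ceil(hi)
    if hi_i <= lo_i:
        hi_i = lo_i + 1
    return float(lo_i), float(hi_i)


def extract_feature_swath(run: SpectraRun, grid: WindowGrid) -> IntensityMatrix:
    """Sum peak intensities per window per scan (unnormalized).

    One row per scan, empty scans included as all-zero rows. Peaks outside
    [mz_min, mz_max] are dropped; their count is logged per run.
    """
    if not run.scans:
        raise ValueError(f"run {run.run_id} has no scans")
    values = np.zeros((run.n_scans, grid.n_windows), dtype=np.float64)
    n_dropped = 0
    for i, scan in enumerate(run.scans):
        if scan.n_peaks == 0:
            continue
        idx = grid.assign(scan.mz)
        keep = idx >= 0
        n_dropped += int((~keep).sum())
        if keep.any():
            values[i] = np.bincount(
                idx[keep], weights=scan.intensity[keep], minlength=grid.n_windows
            )
    if n_dropped:
        logger.info("run %s: dropped %d peak(s) outside [%g, %g]",
                    run.run_id, n_dropped, grid.mz_min, grid.mz_max)
    row_ids = [(run.run_id, s.scan_index) for s in run.scans]
    return IntensityMatrix(values=values, row_ids=row_ids, grid=grid, normalized=False)


def concat_matrices(matrices: list[IntensityMatrix]) -> IntensityMatrix:
    """Stack matrices row-wise; all must share one grid and normalization state."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    grid = matrices[0].grid
    norm = matrices[0].normalized
    if any(m.grid != grid or m.normalized != norm for m in matrices):
        raise ValueError("matrices differ in grid or normalization state")
    return IntensityMatrix(
        values=np.vstack([m.values for m in matrices]),
        row_ids=[rid for m in matrices for rid in m.row_ids],
        grid=grid,
        normalized=norm,
    )


def normalize_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each row by its own maximum; all-zero rows stay all-zero.

    Double normalization is refused: per-scan division is defined on the raw
    summed intensities only.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    row_max = matrix.values.max(axis=1, keepdims=True)
    safe = np.where(row_max > 0, row_max, 1.0)
    return IntensityMatrix(
        values=matrix.values / safe,
        row_ids=list(matrix.row_ids),
        grid=matrix.grid,
        normalized=True,
    )


def make_label_vector(run: SpectraRun, n_rows: int) -> np.ndarray:
    """Repeat the run's sample label once per matrix row."""
    if n_rows != run.n_scans:
        raise ValueError(
            f"run {run.run_id}: n_rows {n_rows} != scan count {run.n_scans}"
        )
    return np.full(n_rows, run.sample_label, dtype=np.int64)
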
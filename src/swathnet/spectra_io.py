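"""Reading LC-MS/MS runs (mzML / mzXML / peak-table CSV) and tabular output.

A *run* is one raw file's ordered scans at a single MS level together with an
integer sample label (e.g. 0 = benign, 1 = tumor). Scans keep their peaks as
parallel m/z / intensity arrays sorted by m/z; empty scans are retained so
that downstream matrices keep one row per acquired scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .mzml_io import MzmlParseError, iter_mzml_spectra

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "SpectrumScan",
    "SpectraRun",
    "ManifestEntry",
    "SampleManifest",
    "SpectraParseError",
    "EmptyRunError",
    "read_spectra",
    "load_manifest",
    "load_runs",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_run_csv",
    "read_run_csv",
]


class SpectraParseError(ValueError):
    """A spectra file could not be read or is in an unsupported dialect."""


class EmptyRunError(ValueError):
    """A file contains no scans at the requested MS level."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class SpectrumScan:
    """One mass spectrum: (m/z, intensity) peaks at a retention time.

    ``mz`` is sorted ascending; ``mz`` and ``intensity`` have equal length
    (possibly zero — empty scans are legal).
    """

    scan_index: int  # 1-based ordinal within the level-filtered run
    ms_level: int
    retention_time: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError("non-positive m/z value")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectraRun:
    """Ordered scans of one raw file at a single MS level, plus its label."""

    run_id: str
    scans: list[SpectrumScan]
    sample_label: int = 0

    def __post_init__(self) -> None:
        idx = [s.scan_index for s in self.scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"run {self.run_id}: scan_index not strictly increasing")
        levels = {s.ms_level for s in self.scans}
        if len(levels) > 1:
            raise ValueError(f"run {self.run_id}: mixed ms_levels {levels}")

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    label: int
    group: str | None = None


@dataclass
class SampleManifest:
    """Cohort description: one row per raw file with its class label."""

    entries: list[ManifestEntry]
    single_class: bool = field(default=False)

    @property
    def labels(self) -> list[int]:
        return [e.label for e in self.entries]

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))


def _rt_to_seconds(value) -> float:
    """Convert a pyteomics unitfloat (or plain number) to seconds."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit is None:
        return v
    unit = str(unit).lower()
    if unit.startswith("min"):
        return v * 60.0
    if unit in ("millisecond", "ms"):
        return v / 1000.0
    return v


def _sniff_dialect(path: Path) -> str:
    head = path.open("rb").read(4096)
    if b"<mzXML" in head:
        return "mzxml"
    if b"<mzML" in head or b"<indexedmzML" in head:
        return "mzml"
    raise SpectraParseError(
        f"{path}: root element is neither mzML nor mzXML (unsupported format)"
    )


def _iter_mzxml(path: Path) -> Iterable[dict]:
    from pyteomics import mzxml  # lazy: only needed for mzXML inputs

    with mzxml.read(str(path)) as reader:
        for scan in reader:
            yield {
                "ms_level": int(scan.get("msLevel", 1)),
                "rt_seconds": _rt_to_seconds(scan.get("retentionTime", float("nan"))),
                "mz": np.asarray(scan["m/z array"], dtype=np.float64),
                "intensity": np.asarray(scan["intensity array"], dtype=np.float64),
            }


def read_spectra(path: str | Path, ms_level: int) -> SpectraRun:
    """Parse an mzML or mzXML file, keeping only scans of ``ms_level``.

    The dialect is auto-detected from the root element. Scans come back in
    acquisition order, re-indexed 1..n within the requested level, peaks
    sorted by m/z and retention times in seconds.

    Raises :class:`SpectraParseError` for unreadable files and
    :class:`EmptyRunError` when the file holds no scans at the level.
    """
    path = Path(path)
    if ms_level not in (1, 2):
        raise ValueError(f"ms_level must be 1 or 2, got {ms_level}")
    if not path.exists():
        raise SpectraParseError(f"{path}: file does not exist")
    dialect = _sniff_dialect(path)
    try:
        raw = _iter_mzxml(path) if dialect == "mzxml" else iter_mzml_spectra(str(path))
        scans: list[SpectrumScan] = []
        n_total = 0
        n_empty = 0
        for record in raw:
            n_total += 1
            if record["ms_level"] != ms_level:
                continue
            if record["mz"].size == 0:
                n_empty += 1
            scans.append(
                SpectrumScan(
                    scan_index=len(scans) + 1,
                    ms_level=ms_level,
                    retention_time=record["rt_seconds"],
                    mz=record["mz"],
                    intensity=record["intensity"],
                )
            )
    except (MzmlParseError, SpectraParseError):
        raise
    except Exception as exc:  # pyteomics raises its own hierarchy
        raise SpectraParseError(f"{path}: failed to parse ({exc})") from exc
    if not scans:
        raise EmptyRunError(
            f"{path}: {n_total} scans read but none at MS level {ms_level}"
        )
    if n_empty:
        logger.info("%s: retained %d empty scan(s) at MS level %d", path, n_empty, ms_level)
    return SpectraRun(run_id=path.stem, scans=scans)


def load_manifest(path: str | Path) -> SampleManifest:
    """Load a ``file,label[,group]`` CSV; paths resolve relative to the CSV.

    Every referenced file must exist and paths must be unique. Fewer than two
    distinct labels only warns here (classification will refuse later).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"file", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    entries: list[ManifestEntry] = []
    seen: set[Path] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        p = Path(str(row.file))
        if not p.is_absolute():
            p = path.parent / p
        if p in seen:
            raise ValueError(f"{path} row {row_no}: duplicate file {p}")
        if not p.exists():
            raise FileNotFoundError(f"{path} row {row_no}: missing file {p}")
        seen.add(p)
        group = str(row.group) if "group" in df.columns and pd.notna(row.group) else None
        entries.append(ManifestEntry(path=p, label=int(row.label), group=group))
    manifest = SampleManifest(entries=entries)
    if manifest.n_classes < 2:
        manifest.single_class = True
        warnings.warn(
            f"{path}: manifest holds a single class; training will be impossible",
            stacklevel=2,
        )
    return manifest


def load_runs(manifest: SampleManifest, ms_level: int) -> list[SpectraRun]:
    """Read every manifest entry (mzML/mzXML/CSV peak table) at ``ms_level``."""
    runs = []
    for entry in manifest.entries:
        if entry.path.suffix.lower() == ".csv":
            run = read_run_csv(entry.path, ms_level=ms_level)
        else:
            run = read_spectra(entry.path, ms_level=ms_level)
        run.sample_label = entry.label
        runs.append(run)
    return runs


def write_matrix_csv(matrix, path: str | Path) -> None:
    """Write an intensity matrix as CSV: run_id, scan_index, then one column
    per m/z window. Values round-trip exactly (shortest-repr floats)."""
    if matrix.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    df = pd.DataFrame(matrix.values, columns=matrix.grid.window_ids())
    df.insert(0, "scan_index", [s for _, s in matrix.row_ids])
    df.insert(0, "run_id", [r for r, _ in matrix.row_ids])
    df.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read back a matrix CSV; returns (id columns frame, value array)."""
    df = pd.read_csv(path)
    ids = df[["run_id", "scan_index"]]
    values = df.drop(columns=["run_id", "scan_index"]).to_numpy(dtype=np.float64)
    return ids, values


def write_run_csv(run: SpectraRun, path: str | Path) -> None:
    """Write a run as a long-format peak table CSV.

    Columns: scan_index, ms_level, retention_time, mz, intensity. Empty scans
    appear as a single row with NaN mz/intensity so they survive round-trips.
    """
    rows = []
    for scan in run.scans:
        if scan.n_peaks == 0:
            rows.append((scan.scan_index, scan.ms_level, scan.retention_time,
                         np.nan, np.nan))
        else:
            for m, i in zip(scan.mz, scan.intensity):
                rows.append((scan.scan_index, scan.ms_level, scan.retention_time, m, i))
    pd.DataFrame(
        rows, columns=["scan_index", "ms_level", "retention_time", "mz", "intensity"]
    ).to_csv(path, index=False)


def read_run_csv(path: str | Path, ms_level: int | None = None) -> SpectraRun:
    """Read a peak-table CSV written by :func:`write_run_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    scans = []
    for (idx, level, rt), g in df.groupby(
        ["scan_index", "ms_level", "retention_time"], sort=False
    ):
        if ms_level is not None and int(level) != ms_level:
            continue
        peaks = g.dropna(subset=["mz"])
        scans.append(
            SpectrumScan(
                scan_index=len(scans) + 1,
                ms_level=int(level),
                retention_time=float(rt),
                mz=peaks["mz"].to_numpy(),
                intensity=peaks["intensity"].to_numpy(),
            )
        )
    if not scans:
        raise EmptyRunError(f"{path}: no scans at MS level {ms_level}")
    return SpectraRun(run_id=path.stem, scans=scans)
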
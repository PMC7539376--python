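"""Synthetic DDA-style cohorts with controllable class separation.

Each run emulates a centroided LC-MS acquisition: scans on a jittered
retention-time grid, a Poisson number of background peaks per scan placed
uniformly in m/z with log-normal intensities, plus *signature* peaks at
class-specific m/z loci. The class signal is controlled by one effect size,
``signature_shift``: class loci are displaced from shared base loci and their
amplitudes rescaled proportionally to it, so ``signature_shift = 0`` makes
all classes distributionally identical by construction (a built-in negative
control). Every run also receives a random global intensity factor, which
per-scan row-max normalization must cancel downstream.

The generator reproduces the features the classifier exploits — class-specific
m/z structure, scan-to-scan variability, per-run scale — but none of the
physics it doesn't: no isotope envelopes, charge states, chromatographic peak
shapes or detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraRun, SpectrumScan

__all__ = [
    "SyntheticConfig",
    "PatternSummary",
    "generate_cohort",
    "pattern_summary",
    "export_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level simulation settings.

    Defaults give a clearly separable 2-class cohort: 5 runs per class,
    300 MS1 scans per run over a 1-hour gradient, ~60 background peaks per
    scan in m/z 350-1350, 8 signature loci per class at full effect size.
    """

    n_runs_per_class: int = 5
    n_classes: int = 2
    scans_per_run: int = 300
    mz_range: tuple[float, float] = (350.0, 1350.0)
    rt_range: tuple[float, float] = (0.0, 3600.0)  # seconds
    n_background_peaks: float = 60.0  # Poisson mean per scan
    n_signature_loci: int = 8  # per class
    signature_shift: float = 1.0  # 0 ⇒ classes identical by construction
    intensity_noise: float = 0.5  # log-normal sigma
    run_scale_jitter: tuple[float, float] = (0.5, 2.0)
    ms2_per_ms1: int = 0  # optional fragment scans per survey scan
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_runs_per_class, self.n_classes, self.scans_per_run,
               self.n_signature_loci) < 1:
            raise ValueError("counts must be positive")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("invalid mz_range")
        if not self.rt_range[0] < self.rt_range[1]:
            raise ValueError("invalid rt_range")
        if self.signature_shift < 0:
            raise ValueError("signature_shift must be >= 0")
        if not 0 < self.run_scale_jitter[0] <= self.run_scale_jitter[1]:
            raise ValueError("invalid run_scale_jitter")


@dataclass
class PatternSummary:
    """Binned intensity landscape of one run over (retention time × m/z)."""

    grid: np.ndarray  # (rt_bins, mz_bins) summed intensities
    rt_edges: np.ndarray
    mz_edges: np.ndarray

    @property
    def rt_marginal(self) -> np.ndarray:
        return self.grid.sum(axis=1)

    @property
    def mz_marginal(self) -> np.ndarray:
        return self.grid.sum(axis=0)


_BG_LOG_MEAN = np.log(1e3)  # background peak median intensity ~1000 counts
_SIG_LOG_MEAN = np.log(8e3)  # signature peaks ~8x brighter than background
_LOCUS_DISPLACEMENT_TH = 5.0  # class locus displacement scale at shift = 1
_PEAK_JITTER_TH = 0.25  # within-scan m/z wobble of a signature peak
_SIG_PRESENCE_P = 0.8  # chance a signature locus fires in a given scan
_FRAGMENTS_PER_MS2 = 12


def _class_signatures(config: SyntheticConfig, rng: np.random.Generator):
    """Per-class (loci, amplitude multipliers); identical across classes at shift 0."""
    lo, hi = config.mz_range
    span = hi - lo
    base = rng.uniform(lo + 0.05 * span, hi - 0.05 * span,
                       size=config.n_signature_loci)
    loci = np.empty((config.n_classes, config.n_signature_loci))
    amps = np.empty_like(loci)
    for c in range(config.n_classes):
        displacement = rng.normal(0.0, _LOCUS_DISPLACEMENT_TH,
                                  size=config.n_signature_loci)
        gamma = rng.normal(0.0, 0.5, size=config.n_signature_loci)
        loci[c] = base + config.signature_shift * displacement
        amps[c] = np.exp(config.signature_shift * gamma)
    return np.clip(loci, lo, hi), amps


def generate_cohort(
    config: SyntheticConfig, ms_level: int = 1
) -> list[SpectraRun]:
    """Generate the cohort's runs at the requested MS level, fully seeded.

    MS1 runs carry the class signal directly. MS2 runs (requires
    ``config.ms2_per_ms1 > 0``) fragment the brightest signature loci into
    fixed-offset fragment peaks with extra intensity noise, so MS2 carries a
    degraded copy of the class signal.
    """
    if ms_level == 2 and config.ms2_per_ms1 < 1:
        raise ValueError("config.ms2_per_ms1 must be >= 1 to generate MS2 runs")
    rng = np.random.default_rng(config.seed)
    loci, amps = _class_signatures(config, rng)
    lo, hi = config.mz_range
    # fragment offsets fixed per locus so MS2 spectra are reproducible structure
    frag_offsets = rng.uniform(-150.0, 150.0,
                               size=(config.n_signature_loci, _FRAGMENTS_PER_MS2))
    runs: list[SpectraRun] = []
    for c in range(config.n_classes):
        for r in range(config.n_runs_per_class):
            run_rng = np.random.default_rng(
                rng.integers(0, 2**31)
            )  # one child stream per run, order-independent of ms_level
            runs.append(
                _generate_run(
                    config, run_rng, run_id=f"class{c}_run{r}", label=c,
                    loci=loci[c], amps=amps[c], frag_offsets=frag_offsets,
                    ms_level=ms_level,
                )
            )
    return runs


def _generate_run(config, rng, run_id, label, loci, amps, frag_offsets, ms_level):
    lo, hi = config.mz_range
    rt_lo, rt_hi = config.rt_range
    run_scale = rng.uniform(*config.run_scale_jitter)
    rt_grid = np.linspace(rt_lo, rt_hi, config.scans_per_run)
    rt_step = (rt_hi - rt_lo) / max(1, config.scans_per_run - 1)
    rt = np.sort(rt_grid + rng.uniform(-0.3, 0.3, size=rt_grid.size) * rt_step)

    scans: list[SpectrumScan] = []
    sigma = config.intensity_noise
    for i in range(config.scans_per_run):
        mz_parts, int_parts = _survey_peaks(config, rng, loci, amps, sigma)
        if ms_level == 1:
            _append_scan(scans, 1, rt[i], mz_parts, int_parts, run_scale, lo, hi)
        else:
            # DDA-style: fragment the brightest loci of this duty cycle
            order = np.argsort(amps)[::-1]
            for k in range(config.ms2_per_ms1):
                locus_idx = order[k % loci.size]
                frag_mz = loci[locus_idx] + frag_offsets[locus_idx]
                frag_int = amps[locus_idx] * np.exp(_SIG_LOG_MEAN) * rng.lognormal(
                    0.0, 1.5 * sigma, size=frag_mz.size
                )
                n_bg = rng.poisson(config.n_background_peaks / 2)
                bg_mz = rng.uniform(lo, hi, size=n_bg)
                bg_int = rng.lognormal(_BG_LOG_MEAN, sigma, size=n_bg)
                _append_scan(
                    scans, 2, rt[i],
                    [frag_mz, bg_mz], [frag_int, bg_int], run_scale, lo, hi,
                )
    return SpectraRun(run_id=run_id, scans=scans, sample_label=label)


def _survey_peaks(config, rng, loci, amps, sigma):
    lo, hi = config.mz_range
    n_bg = rng.poisson(config.n_background_peaks)
    bg_mz = rng.uniform(lo, hi, size=n_bg)
    bg_int = rng.lognormal(_BG_LOG_MEAN, sigma, size=n_bg)
    present = rng.random(loci.size) < _SIG_PRESENCE_P
    sig_mz = loci[present] + rng.normal(0.0, _PEAK_JITTER_TH, size=int(present.sum()))
    sig_int = amps[present] * np.exp(_SIG_LOG_MEAN) * rng.lognormal(
        0.0, sigma, size=int(present.sum())
    )
    return [bg_mz, sig_mz], [bg_int, sig_int]


def _append_scan(scans, ms_level, rt, mz_parts, int_parts, run_scale, lo, hi):
    mz = np.concatenate(mz_parts)
    intensity = np.concatenate(int_parts) * run_scale
    keep = (mz >= lo) & (mz <= hi)
    scans.append(
        SpectrumScan(
            scan_index=len(scans) + 1,
            ms_level=ms_level,
            retention_time=float(rt),
            mz=mz[keep],
            intensity=intensity[keep],
        )
    )


def pattern_summary(run: SpectraRun, rt_bins: int, mz_bins: int) -> PatternSummary:
    """2-D intensity histogram over (retention time × m/z) with marginals.

    Uses the same half-open binning convention as feature extraction, so at a
    matching grid the m/z marginal equals the column sums of the swath
    matrix.
    """
    if not run.scans or all(s.n_peaks == 0 for s in run.scans):
        raise ValueError(f"run {run.run_id} has no peaks to summarize")
    if rt_bins < 1 or mz_bins < 1:
        raise ValueError("bin counts must be positive")
    rt = np.concatenate([np.full(s.n_peaks, s.retention_time) for s in run.scans])
    mz = np.concatenate([s.mz for s in run.scans])
    intensity = np.concatenate([s.intensity for s in run.scans])
    rt_edges = np.linspace(rt.min(), max(rt.max(), rt.min() + 1e-9), rt_bins + 1)
    mz_lo = np.floor(mz.min())
    mz_hi = np.ceil(mz.max())
    if mz_hi <= mz_lo:
        mz_hi = mz_lo + 1
    mz_edges = np.linspace(mz_lo, mz_hi, mz_bins + 1)
    grid, _, _ = np.histogram2d(rt, mz, bins=(rt_edges, mz_edges), weights=intensity)
    return PatternSummary(grid=grid, rt_edges=rt_edges, mz_edges=mz_edges)


def write_pattern_csv(summary: PatternSummary, path) -> None:
    """Grid as CSV: header of m/z bin midpoints, one row per RT bin."""
    import pandas as pd

    mz_mid = 0.5 * (summary.mz_edges[:-1] + summary.mz_edges[1:])
    rt_mid = 0.5 * (summary.rt_edges[:-1] + summary.rt_edges[1:])
    df = pd.DataFrame(summary.grid, columns=[f"mz_{m:.2f}" for m in mz_mid])
    df.insert(0, "rt_s", rt_mid)
    df.to_csv(path, index=False)


def plot_pattern(summary: PatternSummary, path) -> None:
    """Heat map of the (RT × m/z) intensity grid with marginal density panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        2, 2, figsize=(8, 6),
        gridspec_kw={"height_ratios": [1, 4], "width_ratios": [4, 1]},
    )
    axes[0, 1].axis("off")
    ax = axes[1, 0]
    ax.imshow(
        summary.grid.T, aspect="auto", origin="lower", cmap="viridis",
        extent=[summary.rt_edges[0], summary.rt_edges[-1],
                summary.mz_edges[0], summary.mz_edges[-1]],
    )
    ax.set_xlabel("retention time (s)")
    ax.set_ylabel("m/z (Th)")
    rt_mid = 0.5 * (summary.rt_edges[:-1] + summary.rt_edges[1:])
    mz_mid = 0.5 * (summary.mz_edges[:-1] + summary.mz_edges[1:])
    axes[0, 0].fill_between(rt_mid, summary.rt_marginal, color="#3b528b", alpha=0.7)
    axes[0, 0].set_xticks([])
    axes[1, 1].fill_betweenx(mz_mid, summary.mz_marginal, color="#3b528b", alpha=0.7)
    axes[1, 1].set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_cohort(config: SyntheticConfig, out_dir, write_mzml_files: bool = False):
    """Write one peak-table CSV per run plus a ``manifest.csv``.

    With ``write_mzml_files`` the runs are additionally emitted as minimal
    mzML for parser integration testing. Returns the manifest path.
    """
    import pandas as pd
    from pathlib import Path

    from .mzml_io import write_mzml
    from .spectra_io import write_run_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    levels = [1] + ([2] if config.ms2_per_ms1 > 0 else [])
    cohorts = {lvl: generate_cohort(config, ms_level=lvl) for lvl in levels}
    rows = []
    for idx, run in enumerate(cohorts[1]):
        frames = []
        for lvl in levels:
            r = cohorts[lvl][idx]
            frames.append(
                pd.DataFrame(
                    [
                        (s.scan_index, s.ms_level, s.retention_time, m, i)
                        for s in r.scans
                        for m, i in zip(s.mz, s.intensity)
                    ],
                    columns=["scan_index", "ms_level", "retention_time",
                             "mz", "intensity"],
                )
            )
        csv_path = out_dir / f"{run.run_id}.csv"
        pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
        rows.append((csv_path.name, run.sample_label, f"class{run.sample_label}"))
        if write_mzml_files:
            spectra = [
                {"ms_level": s.ms_level, "rt_seconds": s.retention_time,
                 "mz": s.mz, "intensity": s.intensity}
                for lvl in levels for s in cohorts[lvl][idx].scans
            ]
            write_mzml(str(out_dir / f"{run.run_id}.mzML"), spectra,
                       run_id=run.run_id)
            rows[-1] = (f"{run.run_id}.mzML", run.sample_label,
                        f"class{run.sample_label}")
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["file", "label", "group"]).to_csv(
        manifest_path, index=False
    )
    return manifest_path
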
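"""Shared fixtures: tiny spectra files built on the fly and the expensive
leave-one-out simulations, computed once per session."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest

from swathnet.cross_prediction import run_loo
from swathnet.dnn_classifier import TrainingConfig
from swathnet.feature_swath import build_window_grid, infer_mz_range
from swathnet.mzml_io import write_mzml
from swathnet.synthetic_data import SyntheticConfig, generate_cohort


def make_mzxml(path, scans) -> None:
    """Author a minimal mzXML 3.x file.

    ``scans``: list of (ms_level, rt_iso8601_duration, [(mz, intensity), ...]).
    Peaks are base64 big-endian float32 pairs per the mzXML spec.
    """
    body = []
    for num, (level, rt, peaks) in enumerate(scans, start=1):
        raw = b"".join(struct.pack(">ff", m, i) for m, i in peaks)
        b64 = base64.b64encode(raw).decode()
        body.append(
            f'<scan num="{num}" msLevel="{level}" peaksCount="{len(peaks)}" '
            f'retentionTime="{rt}">'
            f'<peaks precision="32" byteOrder="network" pairOrder="m/z-int">'
            f"{b64}</peaks></scan>"
        )
    doc = (
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">'
        f'<msRun scanCount="{len(scans)}">{"".join(body)}</msRun></mzXML>'
    )
    path.write_text(doc)


def make_mzml_with_unit(path, scans, rt_unit="minute") -> None:
    """Author mzML directly (bypassing the package writer) with a chosen RT unit."""
    spectra = []
    for level, rt_value, peaks in scans:
        mz = np.array([m for m, _ in peaks])
        spectra.append({"ms_level": level, "rt_seconds": rt_value, "mz": mz,
                        "intensity": np.array([i for _, i in peaks])})
    write_mzml(str(path), spectra)
    if rt_unit != "second":
        text = path.read_text()
        text = text.replace('unitAccession="UO:0000010" unitName="second"',
                            'unitAccession="UO:0000031" unitName="minute"')
        path.write_text(text)


@pytest.fixture()
def mixed_level_mzml(tmp_path):
    """An mzML file with 3 MS1 and 5 MS2 scans of known content."""
    path = tmp_path / "mixed.mzML"
    rng = np.random.default_rng(42)
    spectra = []
    for k in range(8):
        level = 1 if k % 3 == 0 else 2  # scans 0,3,6 are MS1 -> 3 MS1 + 5 MS2
        n = int(rng.integers(2, 6))
        mz = np.sort(rng.uniform(300, 1200, n))
        spectra.append({"ms_level": level, "rt_seconds": 10.0 * (k + 1),
                        "mz": mz, "intensity": rng.uniform(1, 1e4, n)})
    write_mzml(str(path), spectra)
    return path, spectra


def random_scans(rng, n_scans, max_peaks=1000, mz_lo=100.0, mz_hi=1500.0):
    """Random centroided scans for binning property tests."""
    from swathnet.spectra_io import SpectrumScan

    scans = []
    for i in range(n_scans):
        n = int(rng.integers(0, max_peaks + 1))
        scans.append(
            SpectrumScan(
                scan_index=i + 1,
                ms_level=1,
                retention_time=float(i),
                mz=np.sort(rng.uniform(mz_lo, mz_hi, n)),
                intensity=rng.uniform(0.0, 1e5, n),
            )
        )
    return scans


@pytest.fixture(scope="session")
def strong_signal_cohort():
    """Default-condition synthetic cohort with full class separation."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def strong_signal_loo(strong_signal_cohort):
    """Leave-one-out result on the default strong-signal cohort (seed 7)."""
    runs = strong_signal_cohort
    grid = build_window_grid(*infer_mz_range(runs), "32x32")
    return run_loo(runs, grid, config=TrainingConfig(seed=7))


@pytest.fixture(scope="session")
def null_signal_loo_results():
    """Leave-one-out results for 10 seeds at zero class separation.

    Full default conditions apart from signature_shift = 0: this is the
    negative control in which classes are identical by construction.
    """
    results = []
    for seed in range(10):
        runs = generate_cohort(SyntheticConfig(signature_shift=0.0, seed=seed))
        grid = build_window_grid(*infer_mz_range(runs), "32x32")
        results.append(run_loo(runs, grid, config=TrainingConfig(seed=seed)))
    return results
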
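"""Minimal mzML 1.1 reader and writer.

Covers the subset of mzML needed for scan-level fingerprinting: per-spectrum
ms level, scan start time (minute/second units), and base64-encoded 32/64-bit
float m/z and intensity arrays with either zlib or no compression. Precursor
metadata, chromatograms and indexed wrappers are ignored on read and never
written.

The writer exists so that synthetic cohorts can be round-tripped through a
real file format in integration tests; files it emits are plain (non-indexed)
mzML 1.1 readable by standard tools.
"""

from __future__ import annotations

import base64
import zlib
from typing import Iterator

import numpy as np
from lxml import etree

__all__ = ["iter_mzml_spectra", "write_mzml", "MzmlParseError"]

_NS = "http://psi.hupo.org/ms/mzml"

# accessions used to interpret binaryDataArray cvParams
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


class MzmlParseError(ValueError):
    """Raised when an mzML document cannot be interpreted."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: etree._Element) -> np.ndarray:
    dtype = None
    compressed = False
    text = ""
    for child in bda:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    if dtype is None:
        # mzML requires a precision term; default to 64-bit like most writers
        dtype = "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _array_role(bda: etree._Element) -> str | None:
    for child in bda:
        if _local(child.tag) == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MZ_ARRAY:
                return "mz"
            if acc == _ACC_INTENSITY_ARRAY:
                return "intensity"
    return None


def _scan_start_seconds(spectrum: etree._Element) -> float:
    for cv in spectrum.iter("{%s}cvParam" % _NS):
        if cv.get("accession") == _ACC_SCAN_START:
            value = float(cv.get("value", "nan"))
            unit = (cv.get("unitName") or "").lower()
            if unit.startswith("min"):
                return value * 60.0
            if unit in ("millisecond", "ms"):
                return value / 1000.0
            return value  # second, or unitless (assume seconds)
    return float("nan")


def iter_mzml_spectra(path: str) -> Iterator[dict]:
    """Stream spectra from an mzML file.

    Yields dicts with keys ``ms_level`` (int), ``rt_seconds`` (float, NaN if
    absent), ``mz`` and ``intensity`` (float64 arrays). Raises
    :class:`MzmlParseError` on documents without mzML spectra.
    """
    n_seen = 0
    try:
        context = etree.iterparse(path, events=("end",), tag="{%s}spectrum" % _NS)
        for _, spectrum in context:
            ms_level = 1
            for cv in spectrum.iter("{%s}cvParam" % _NS):
                if cv.get("accession") == _ACC_MS_LEVEL:
                    ms_level = int(cv.get("value", "1"))
                    break
            mz = np.empty(0)
            intensity = np.empty(0)
            for bda in spectrum.iter("{%s}binaryDataArray" % _NS):
                role = _array_role(bda)
                if role == "mz":
                    mz = _decode_binary(bda)
                elif role == "intensity":
                    intensity = _decode_binary(bda)
            yield {
                "ms_level": ms_level,
                "rt_seconds": _scan_start_seconds(spectrum),
                "mz": mz,
                "intensity": intensity,
            }
            n_seen += 1
            spectrum.clear()
    except etree.XMLSyntaxError as exc:
        raise MzmlParseError(f"{path}: not well-formed XML ({exc})") from exc
    if n_seen == 0:
        raise MzmlParseError(f"{path}: no <spectrum> elements in the mzML namespace")


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(path: str, spectra: list[dict], run_id: str = "run") -> None:
    """Write spectra (dicts as yielded by :func:`iter_mzml_spectra`) as mzML 1.1.

    Arrays are stored uncompressed as 64-bit floats; retention times are
    written in seconds with an explicit unit.
    """
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_NS}" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        f'<run id="{run_id}">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for idx, spec in enumerate(spectra):
        mz = np.asarray(spec["mz"], dtype=np.float64)
        intensity = np.asarray(spec["intensity"], dtype=np.float64)
        rt = float(spec.get("rt_seconds", 0.0))
        mz_b64 = _b64(mz)
        int_b64 = _b64(intensity)
        parts += [
            f'<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{mz.size}">',
            f'<cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" '
            f'value="{int(spec.get("ms_level", 1))}"/>',
            '<scanList count="1"><scan>',
            f'<cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
            f'value="{rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>',
            "</scan></scanList>",
            '<binaryDataArrayList count="2">',
            f'<binaryDataArray encodedLength="{len(mz_b64)}">',
            f'<cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>',
            f'<cvParam cvRef="MS" accession="{_ACC_NONE}" name="no compression" value=""/>',
            f'<cvParam cvRef="MS" accession="{_ACC_MZ_ARRAY}" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
            f"<binary>{mz_b64}</binary>",
            "</binaryDataArray>",
            f'<binaryDataArray encodedLength="{len(int_b64)}">',
            f'<cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>',
            f'<cvParam cvRef="MS" accession="{_ACC_NONE}" name="no compression" value=""/>',
            f'<cvParam cvRef="MS" accession="{_ACC_INTENSITY_ARRAY}" name="intensity array" '
            'value="" unitCvRef="MS" unitAccession="MS:1000131" '
            'unitName="number of detector counts"/>',
            f"<binary>{int_b64}</binary>",
            "</binaryDataArray>",
            "</binaryDataArrayList>",
            "</spectrum>",
        ]
    parts += ["</spectrumList>", "</run>", "</mzML>", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))
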
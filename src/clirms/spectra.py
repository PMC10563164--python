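"""Precursor-level operations on mzXML data.

Covers reading MS2 precursor records, detecting light/heavy isotope scan
pairs at expected delta masses, and producing m/z-shifted decoy runs.

The mzXML reader/writer here is deliberately minimal: it handles the
scan-level metadata and peak arrays this pipeline needs (msLevel,
retentionTime, precursorMz/@precursorCharge, base64 peak data at 32- or
64-bit precision, optional zlib compression) and nothing else.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "PrecursorRecord",
    "ScanPair",
    "MzxmlScan",
    "read_mzxml_scans",
    "write_mzxml",
    "read_precursors",
    "find_isotope_pairs",
    "shift_mz_decoy",
    "write_scan_pairs",
]


@dataclass(frozen=True)
class PrecursorRecord:
    """One MS2 scan's precursor metadata."""

    scan_id: int
    precursor_mz: float
    charge: int
    retention_time_s: float
    source_file: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be > 0")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.retention_time_s < 0:
            raise ValueError("retention_time must be >= 0")


@dataclass(frozen=True)
class ScanPair:
    """A light/heavy precursor pair matched to an expected delta mass."""

    light_scan: int
    heavy_scan: int
    delta_mass_da: float
    ppm_error: float
    rt_gap_s: float
    charge: int


@dataclass
class MzxmlScan:
    """In-memory representation of one mzXML scan."""

    num: int
    ms_level: int
    retention_time_s: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    extra: Dict[str, str] = field(default_factory=dict)


_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


def _decode_peaks(
    text: str, precision: int, compression: str | None
) -> Tuple[np.ndarray, np.ndarray]:
    raw = base64.b64decode(text.strip()) if text and text.strip() else b""
    if compression and compression.lower() == "zlib":
        raw = zlib.decompress(raw)
    dtype = ">f8" if precision == 64 else ">f4"
    arr = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    return arr[0::2].copy(), arr[1::2].copy()


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray, precision: int) -> str:
    interleaved = np.empty(2 * len(mz), dtype=np.float64)
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    dtype = ">f8" if precision == 64 else ">f4"
    return base64.b64encode(interleaved.astype(dtype).tobytes()).decode()


def _parse_rt(value: str) -> float:
    # mzXML retentionTime is ISO-8601 duration, e.g. "PT612.3S"
    v = value.strip()
    if v.startswith("PT") and v.endswith("S"):
        return float(v[2:-1])
    return float(v)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_mzxml_scans(path) -> List[MzxmlScan]:
    """Parse all scans (any msLevel) from an mzXML file."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"invalid mzXML file {path}: {exc}") from exc
    scans: List[MzxmlScan] = []
    for el in tree.getroot().iter():
        if _localname(el.tag) != "scan":
            continue
        num = int(el.get("num"))
        ms_level = int(el.get("msLevel", "1"))
        rt = _parse_rt(el.get("retentionTime", "PT0S"))
        precursor_mz = None
        precursor_charge = None
        mz = np.empty(0)
        intensity = np.empty(0)
        for child in el:
            name = _localname(child.tag)
            if name == "precursorMz":
                precursor_mz = float(child.text)
                ch = child.get("precursorCharge")
                precursor_charge = int(ch) if ch is not None else None
            elif name == "peaks":
                precision = int(child.get("precision", "32"))
                compression = child.get("compressionType")
                mz, intensity = _decode_peaks(
                    child.text or "", precision, compression
                )
        scans.append(
            MzxmlScan(
                num=num,
                ms_level=ms_level,
                retention_time_s=rt,
                mz=mz,
                intensity=intensity,
                precursor_mz=precursor_mz,
                precursor_charge=precursor_charge,
            )
        )
    scans.sort(key=lambda s: s.num)
    return scans


def write_mzxml(scans: Sequence[MzxmlScan], path, precision: int = 64) -> None:
    """Write scans as a minimal (uncompressed) mzXML 3.2 document."""
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        f'<mzXML xmlns="{_NS}">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for s in scans:
        lines.append(
            f'  <scan num="{s.num}" msLevel="{s.ms_level}" '
            f'peaksCount="{len(s.mz)}" '
            f'retentionTime="PT{s.retention_time_s:.4f}S">'
        )
        if s.ms_level >= 2 and s.precursor_mz is not None:
            charge_attr = (
                f' precursorCharge="{s.precursor_charge}"'
                if s.precursor_charge is not None
                else ""
            )
            lines.append(
                f"   <precursorMz{charge_attr}>"
                f"{s.precursor_mz:.8f}</precursorMz>"
            )
        payload = _encode_peaks(s.mz, s.intensity, precision)
        lines.append(
            f'   <peaks precision="{precision}" byteOrder="network" '
            f'contentType="m/z-int">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines.append(" </msRun>")
    lines.append("</mzXML>")
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")


def read_precursors(mzxml_path) -> List[PrecursorRecord]:
    """Extract one PrecursorRecord per MS2 scan, ordered by scan id.

    MS2 scans lacking precursor m/z or charge are skipped with a warning.
    """
    import warnings

    scans = read_mzxml_scans(mzxml_path)
    records = []
    skipped = 0
    for s in scans:
        if s.ms_level != 2:
            continue
        if s.precursor_mz is None or s.precursor_charge is None:
            skipped += 1
            continue
        records.append(
            PrecursorRecord(
                scan_id=s.num,
                precursor_mz=s.precursor_mz,
                charge=s.precursor_charge,
                retention_time_s=s.retention_time_s,
                source_file=str(mzxml_path),
            )
        )
    if skipped:
        warnings.warn(
            f"{skipped} MS2 scan(s) lacked precursor metadata and were "
            f"skipped",
            stacklevel=2,
        )
    records.sort(key=lambda r: r.scan_id)
    return records


def find_isotope_pairs(
    records: Sequence[PrecursorRecord],
    deltas: Sequence[float],
    ppm_tol: float = 10.0,
    rt_tol_s: float = 60.0,
) -> List[ScanPair]:
    """All light/heavy precursor pairs matching an expected delta mass.

    A pair (light, heavy) requires equal charge z, retention-time gap
    within ``rt_tol_s``, and ``(heavy_mz - light_mz) * z`` within
    ``ppm_tol`` of some delta, with the ppm error referenced to the light
    neutral mass: ``ppm = |(heavy-light)*z - delta| / (light*z) * 1e6``.
    The list is exhaustive (a scan may participate in several pairs) and
    sorted by (light_scan, heavy_scan).
    """
    if ppm_tol <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be > 0")
    deltas = sorted(float(d) for d in deltas)
    if any(d <= 0 for d in deltas):
        raise ValueError("delta masses must be > 0")
    if not records or not deltas:
        return []

    by_charge: Dict[int, List[PrecursorRecord]] = {}
    for r in records:
        by_charge.setdefault(r.charge, []).append(r)

    pairs: List[ScanPair] = []
    max_delta = deltas[-1]
    for z, recs in by_charge.items():
        recs = sorted(recs, key=lambda r: r.precursor_mz)
        mzs = [r.precursor_mz for r in recs]
        for i, light in enumerate(recs):
            # generous m/z window; exact ppm test below
            limit = light.precursor_mz + max_delta / z + 1.0
            j = i + 1
            while j < len(recs) and mzs[j] <= limit:
                heavy = recs[j]
                j += 1
                if heavy.scan_id == light.scan_id:
                    continue
                if abs(heavy.retention_time_s - light.retention_time_s) > rt_tol_s:
                    continue
                observed = (heavy.precursor_mz - light.precursor_mz) * z
                light_neutral = light.precursor_mz * z
                for d in deltas:
                    ppm = abs(observed - d) / light_neutral * 1e6
                    if ppm <= ppm_tol:
                        pairs.append(
                            ScanPair(
                                light_scan=light.scan_id,
                                heavy_scan=heavy.scan_id,
                                delta_mass_da=d,
                                ppm_error=ppm,
                                rt_gap_s=abs(
                                    heavy.retention_time_s
                                    - light.retention_time_s
                                ),
                                charge=z,
                            )
                        )
    pairs.sort(key=lambda p: (p.light_scan, p.heavy_scan, p.delta_mass_da))
    return pairs


def shift_mz_decoy(mzxml_in, mzxml_out, shift: float = 10.0) -> Dict[str, int]:
    """Write a decoy run with every m/z value shifted by ``shift``.

    Precursor and fragment m/z values are shifted; retention times,
    intensities, charges and scan numbering are preserved.  Returns a
    summary dict with scan and peak counts.
    """
    scans = read_mzxml_scans(mzxml_in)
    n_peaks = 0
    for s in scans:
        if len(s.mz) and float(np.min(s.mz)) + shift <= 0:
            raise ValueError(
                f"shift {shift} would produce non-positive fragment m/z in "
                f"scan {s.num}"
            )
        if s.precursor_mz is not None and s.precursor_mz + shift <= 0:
            raise ValueError(
                f"shift {shift} would produce non-positive precursor m/z in "
                f"scan {s.num}"
            )
    for s in scans:
        s.mz = s.mz + shift
        if s.precursor_mz is not None:
            s.precursor_mz += shift
        n_peaks += len(s.mz)
    write_mzxml(scans, mzxml_out)
    return {"scans": len(scans), "peaks": n_peaks}


def write_scan_pairs(pairs: Sequence[ScanPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "light_scan\theavy_scan\tdelta_da\tppm_error\trt_gap_s\tcharge\n"
        )
        for p in pairs:
            fh.write(
                f"{p.light_scan}\t{p.heavy_scan}\t{p.delta_mass_da:.6f}\t"
                f"{p.ppm_error:.4f}\t{p.rt_gap_s:.2f}\t{p.charge}\n"
            )
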
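"""Spectral I/O: MGF peak lists for MS2 and a tidy CSV for MS1 scans.

MGF (Mascot generic format) is the MS2 interchange format, read and
written through :mod:`pyteomics.mgf` with the PEPMASS/CHARGE/RTINSECONDS
keys.  The MS1 scan series travels as a plain CSV with columns
``rt_seconds,mz,intensity`` (comma-separated, header row, '.' decimal),
one row per peak, scans ordered by strictly increasing retention time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

DEFAULT_CHARGE = 2


@dataclass
class Ms2Spectrum:
    """One tandem spectrum: precursor plus an m/z-sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.spectrum_id}: negative intensities")
        if not 1 <= self.precursor_charge <= 4:
            raise ValueError(
                f"{self.spectrum_id}: precursor charge {self.precursor_charge} outside 1..4"
            )

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Ms1Trace:
    """A series of MS1 scans: (retention time, mz array, intensity array)."""

    scans: List[Tuple[float, np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s[0] for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("MS1 scans must be sorted by strictly increasing retention time")

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s[0] for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


def read_mgf(path) -> List[Ms2Spectrum]:
    """Read an MGF file into a list of spectra.

    A block without a CHARGE line defaults to 2+ with a logged warning.
    Malformed blocks raise ``ValueError`` naming the file.
    """
    spectra: List[Ms2Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                title = str(params.get("title", f"spectrum_{i}"))
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise ValueError(f"{path}: block {title!r} missing PEPMASS")
                charge_field = params.get("charge")
                if charge_field:
                    charge = int(charge_field[0])
                else:
                    charge = DEFAULT_CHARGE
                    logger.warning(
                        "%s: block %r missing CHARGE, defaulting to %d+", path, title, DEFAULT_CHARGE
                    )
                rt = float(params.get("rtinseconds", 0.0))
                spectra.append(
                    Ms2Spectrum(
                        spectrum_id=title,
                        precursor_mz=float(pepmass[0]),
                        precursor_charge=charge,
                        retention_time=rt,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed MGF {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path) -> None:
    """Write spectra to MGF; round-trips with :func:`read_mgf` within 1e-6."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": s.precursor_charge,
                "rtinseconds": s.retention_time,
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def read_ms1_csv(path) -> Ms1Trace:
    """Read an MS1 trace from CSV (columns rt_seconds, mz, intensity).

    Rows with equal ``rt_seconds`` form one scan; retention times must
    appear in non-decreasing order, or the offending row is named.
    """
    df = pd.read_csv(path)
    required = {"rt_seconds", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if len(df) == 0:
        return Ms1Trace([])
    rt = df["rt_seconds"].to_numpy()
    drops = np.nonzero(np.diff(rt) < 0)[0]
    if drops.size:
        line = int(drops[0]) + 3  # offending row, counting the header as line 1
        raise ValueError(f"{path}: retention time decreases at line {line}")
    scans = [
        (float(rt_val), g["mz"].to_numpy(), g["intensity"].to_numpy())
        for rt_val, g in df.groupby("rt_seconds", sort=True)
    ]
    return Ms1Trace(scans)


def write_ms1_csv(trace: Ms1Trace, path) -> None:
    """Write an MS1 trace as CSV; lossless round-trip at 6 d.p."""
    rows = []
    for rt, mz_arr, int_arr in trace.scans:
        for m, inten in zip(mz_arr, int_arr):
            rows.append((round(rt, 6), round(float(m), 6), round(float(inten), 6)))
    pd.DataFrame(rows, columns=["rt_seconds", "mz", "intensity"]).to_csv(path, index=False)
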
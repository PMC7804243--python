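"""MS/MS spectrum container, normalization, intensity floor and MGF/CSV I/O.

Spectra are NO3−-CI product-ion scans: a precursor adduct ([M·NO3]− or
[M·HNO3NO3]−), the declustered reagent ion NO3−, and fragment ions.
Relative intensities are base-peak normalized and refined with a relative
intensity floor (0.1% by default); the precursor and reagent-ion peaks are
never dropped by the floor, since they carry the declustering information
rather than analyte structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .formula import ElementFormula, NO3, mz as formula_mz, ppm_error

__all__ = [
    "Peak",
    "MsmsSpectrum",
    "normalize",
    "filter_floor",
    "read_mgf",
    "write_mgf",
    "read_peaks_csv",
    "write_peaks_csv",
]

NO3_MZ = formula_mz(ElementFormula(n=1, o=3, charge=-1))

#: centroids closer than this (in m/z) are merged on construction
MERGE_TOLERANCE = 1e-5

ADDUCTS = ("NO3", "HNO3NO3")


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    rel_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class MsmsSpectrum:
    """One product-ion spectrum of a single NO3−-CI precursor.

    ``nce`` is the instrument's normalized collision energy (dimensionless,
    typically 2–10 for these adducts).  Peaks are kept sorted by m/z and
    near-duplicate centroids (within ``MERGE_TOLERANCE``) are merged with
    summed intensity.
    """

    label: str
    precursor_mz: float
    adduct: str = "NO3"
    nce: float = 0.0
    peaks: list[Peak] = field(default_factory=list)
    precursor_formula: ElementFormula | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.label!r}: precursor m/z must be positive")
        if self.nce < 0:
            raise ValueError(f"{self.label!r}: NCE must be non-negative")
        if self.adduct not in ADDUCTS:
            raise ValueError(f"{self.label!r}: unknown adduct {self.adduct!r}")
        self.peaks = _merge_sorted(self.peaks)

    @property
    def base_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    def is_normalized(self) -> bool:
        return bool(self.peaks) and all(p.rel_intensity is not None for p in self.peaks)


def _merge_sorted(peaks: Sequence[Peak]) -> list[Peak]:
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda q: q.mz):
        if out and p.mz - out[-1].mz <= MERGE_TOLERANCE:
            prev = out[-1]
            total = prev.intensity + p.intensity
            weighted = prev.mz if total == 0 else (
                (prev.mz * prev.intensity + p.mz * p.intensity) / total)
            out[-1] = Peak(weighted, total)
        else:
            out.append(p)
    return out


def normalize(s: MsmsSpectrum) -> MsmsSpectrum:
    """Base-peak normalization: rel_intensity = intensity / max intensity.

    Idempotent; raises on an empty or all-zero spectrum.
    """
    base = s.base_intensity
    if base <= 0:
        raise ValueError(f"{s.label!r}: cannot normalize an all-zero spectrum")
    peaks = [replace(p, rel_intensity=p.intensity / base) for p in s.peaks]
    return replace(s, peaks=peaks)


def filter_floor(s: MsmsSpectrum, floor: float = 0.001,
                 tolerance_ppm: float = 5.0) -> MsmsSpectrum:
    """Drop peaks below the relative-intensity floor (inclusive boundary:
    rel ≥ floor survives).  The precursor and NO3− reagent-ion peaks are
    always retained.
    """
    if not s.is_normalized():
        raise ValueError(f"{s.label!r}: normalize before applying the floor")

    def protected(p: Peak) -> bool:
        return (abs(ppm_error(s.precursor_mz, p.mz)) <= tolerance_ppm
                or abs(ppm_error(NO3_MZ, p.mz)) <= tolerance_ppm)

    peaks = [p for p in s.peaks
             if p.rel_intensity >= floor or protected(p)]
    return replace(s, peaks=peaks)


# ---------------------------------------------------------------------------
# MGF I/O (standard dialect, CHARGE=1-; NCE/ADDUCT/LABEL as key-value lines)
# ---------------------------------------------------------------------------

def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": [p.mz for p in s.peaks],
            "intensity array": [p.intensity for p in s.peaks],
            "params": {
                "title": s.label,
                "pepmass": (s.precursor_mz,),
                "charge": "1-",
                "nce": s.nce,
                "adduct": s.adduct,
            },
        })
    _mgf.write(entries, str(path), fragment_format="%.6f %.10g",
               write_charges=False, file_mode="w")


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file; each block must carry PEPMASS and CHARGE=1-."""
    spectra: list[MsmsSpectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"scan {i + 1}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"MGF block {title!r}: missing PEPMASS")
            peaks = [Peak(float(m), float(inten)) for m, inten in
                     zip(entry["m/z array"], entry["intensity array"])]
            spectra.append(MsmsSpectrum(
                label=title,
                precursor_mz=float(pepmass[0]),
                adduct=str(params.get("adduct", "NO3")),
                nce=float(params.get("nce", 0.0)),
                peaks=peaks,
            ))
    return spectra


# ---------------------------------------------------------------------------
# Two-column CSV peak lists (header required: mz,intensity)
# ---------------------------------------------------------------------------

def write_peaks_csv(s: MsmsSpectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": [p.mz for p in s.peaks],
                  "intensity": [p.intensity for p in s.peaks]}
                 ).to_csv(path, index=False, float_format="%.6f")


def read_peaks_csv(path: str | Path, label: str, precursor_mz: float,
                   adduct: str = "NO3", nce: float = 0.0) -> MsmsSpectrum:
    frame = pd.read_csv(path)
    required = {"mz", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: CSV peak list needs columns {sorted(required)}")
    peaks = [Peak(float(r.mz), float(r.intensity)) for r in frame.itertuples()]
    return MsmsSpectrum(label=label, precursor_mz=precursor_mz,
                        adduct=adduct, nce=nce, peaks=peaks)
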
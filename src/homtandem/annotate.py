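"""Formula assignment for precursor and product ions, and the neutral-loss table.

The precursor composition is found by constrained enumeration over
C/H/N/O space (≤ 2 N, to accommodate the NO3−/HNO3NO3− adduct nitrogen);
each product ion is then assigned the best element-wise sub-formula of
the precursor within the ppm tolerance.  Neutral losses are single-step
precursor-minus-product differences — multi-step cascades (e.g. O2
followed by CHO3) are interpreted downstream by the rule engine, not
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formula import (ELECTRON_MASS, ElementFormula, EnumerationBounds,
                      _MASS_VECTOR, enumerate_formulas, mz as formula_mz,
                      ppm_error, subtract)
from .spectrum import MsmsSpectrum, NO3_MZ, Peak

__all__ = ["AnnotatedPeak", "assign_precursor", "annotate_products",
           "loss_table", "annotation_frame"]

ROLES = ("precursor", "reagent_ion", "product", "unassigned")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    formula: ElementFormula | None
    ppm: float | None
    neutral_loss: ElementFormula | None
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


def assign_precursor(s: MsmsSpectrum,
                     bounds: EnumerationBounds | None = None,
                     include_electron: bool = True) -> ElementFormula:
    """Best-ranked formula for the precursor m/z; stored on the spectrum.

    Raises with a nearest-candidate diagnostic when nothing falls inside
    the ppm tolerance.
    """
    bounds = bounds or EnumerationBounds()
    candidates = enumerate_formulas(s.precursor_mz, bounds,
                                    include_electron=include_electron)
    if not candidates:
        wide = EnumerationBounds(c=bounds.c, h=bounds.h, n=bounds.n, o=bounds.o,
                                 rdbe_range=bounds.rdbe_range,
                                 tolerance_ppm=1000.0)
        near = enumerate_formulas(s.precursor_mz, wide,
                                  include_electron=include_electron)
        hint = f"; nearest candidate {near[0]} at " \
               f"{ppm_error(formula_mz(near[0], include_electron), s.precursor_mz):+.1f} ppm" \
            if near else ""
        raise ValueError(
            f"{s.label!r}: no formula within {bounds.tolerance_ppm} ppm of "
            f"precursor m/z {s.precursor_mz}{hint}")
    best = candidates[0]
    s.precursor_formula = best
    return best


def _subformula_table(parent: ElementFormula) -> tuple[np.ndarray, np.ndarray]:
    axes = [np.arange(getattr(parent, e) + 1) for e in ("c", "h", "n", "o")]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    mass = grid @ _MASS_VECTOR + ELECTRON_MASS
    return grid, mass


def _best_subformula(grid: np.ndarray, mass: np.ndarray, target_mz: float,
                     tolerance_ppm: float) -> tuple[ElementFormula, float] | None:
    ppm = 1e6 * (target_mz - mass) / mass
    ok = np.abs(ppm) <= tolerance_ppm
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    # ties: smaller |ppm|, then fewer N, then fewer O (then C, H for
    # full determinism)
    order = np.lexsort((grid[idx, 1], grid[idx, 0], grid[idx, 3],
                        grid[idx, 2], np.abs(ppm[idx])))
    i = idx[order[0]]
    f = ElementFormula(*(int(v) for v in grid[i]), charge=-1)
    return f, float(ppm[i])


def annotate_products(s: MsmsSpectrum, parent: ElementFormula | None = None,
                      tolerance_ppm: float = 5.0) -> list[AnnotatedPeak]:
    """Assign each peak the best sub-formula of the precursor composition.

    The peak matching NO3− is tagged ``reagent_ion``; the peak matching
    the precursor is tagged ``precursor``; peaks with no sub-formula in
    the ppm window stay ``unassigned`` (kept in the output).  Product
    ions may be even- or odd-electron; no electron-parity filter is
    applied.
    """
    parent = parent or s.precursor_formula
    if parent is None:
        raise ValueError(f"{s.label!r}: assign the precursor formula first")
    grid, mass = _subformula_table(parent)
    parent_mz = formula_mz(parent)
    out: list[AnnotatedPeak] = []
    for p in s.peaks:
        if abs(ppm_error(NO3_MZ, p.mz)) <= tolerance_ppm:
            out.append(AnnotatedPeak(p, ElementFormula(n=1, o=3, charge=-1),
                                     ppm_error(NO3_MZ, p.mz), None, "reagent_ion"))
            continue
        if abs(ppm_error(parent_mz, p.mz)) <= tolerance_ppm:
            out.append(AnnotatedPeak(p, parent, ppm_error(parent_mz, p.mz),
                                     None, "precursor"))
            continue
        hit = _best_subformula(grid, mass, p.mz, tolerance_ppm)
        if hit is None:
            out.append(AnnotatedPeak(p, None, None, None, "unassigned"))
        else:
            f, ppm = hit
            out.append(AnnotatedPeak(p, f, ppm, subtract(parent, f), "product"))
    return out


def loss_table(annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    """One row per distinct neutral-loss composition.

    Losses are single-step (precursor minus product); reagent-ion and
    precursor peaks are excluded; equal-loss products have their relative
    intensities summed.
    """
    rows: dict[str, dict] = {}
    for a in annotated:
        if a.role != "product" or a.neutral_loss is None:
            continue
        key = str(a.neutral_loss)
        rel = a.peak.rel_intensity or 0.0
        row = rows.setdefault(key, {"loss": key, "rel_intensity": 0.0,
                                    "product_formulas": []})
        row["rel_intensity"] += rel
        row["product_formulas"].append(str(a.formula))
    frame = pd.DataFrame(rows.values(),
                         columns=["loss", "rel_intensity", "product_formulas"])
    if len(frame):
        frame["product_formulas"] = frame["product_formulas"].map(
            lambda fs: ";".join(sorted(set(fs))))
        frame = frame.sort_values("rel_intensity", ascending=False,
                                  kind="stable").reset_index(drop=True)
    return frame


def annotation_frame(label: str, annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    """Flat table (one row per peak) for CSV export."""
    return pd.DataFrame([{
        "spectrum": label,
        "mz": a.peak.mz,
        "rel_intensity": a.peak.rel_intensity,
        "formula": "" if a.formula is None else str(a.formula),
        "ppm": np.nan if a.ppm is None else a.ppm,
        "role": a.role,
        "neutral_loss": "" if a.neutral_loss is None else str(a.neutral_loss),
    } for a in annotated])
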
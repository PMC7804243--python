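"""Elemental-formula arithmetic for C/H/N/O anions.

Everything downstream — peak annotation, neutral-loss derivation, the
fragmentation rule engine — runs on :class:`ElementFormula`, a fixed
C/H/N/O composition with an optional −1 charge and an odd-electron
(radical) flag.  Nitrate chemical ionization produces [M·NO3]− clusters,
which are represented throughout by their *combined* composition
(C10H15O8·NO3− ≡ C10H15NO11−); peroxy-radical adducts are odd-electron
and carry ``radical=True``.

Monoisotopic masses use the standard reference values (CODATA electron
mass, IUPAC 2021 atomic masses for the principal isotopes).  Anion m/z is
electron-inclusive by default: measured Orbitrap m/z values of these
adducts fall within the instrument's ~2 ppm accuracy of the
electron-inclusive theoretical mass, and all matching in this package is
tolerance-based (5 ppm default), never exact-decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC",
    "ElementFormula",
    "EnumerationBounds",
    "NO3",
    "HNO3",
    "parse_formula",
    "monoisotopic_mass",
    "mz",
    "ppm_error",
    "rdbe",
    "enumerate_formulas",
    "nitrate_adduct",
]

#: Monoisotopic masses of the principal isotopes, in Da.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

_ELEMENTS = ("c", "h", "n", "o")
_MASS_VECTOR = np.array([MONOISOTOPIC[e.upper()] for e in _ELEMENTS])


@dataclass(frozen=True)
class ElementFormula:
    """A C/H/N/O composition with charge (0 or −1) and radical flag.

    The all-zero formula is the identity for addition and subtraction.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    charge: int = 0
    radical: bool = False

    def __post_init__(self) -> None:
        for e in _ELEMENTS:
            v = getattr(self, e)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {e}={v!r} must be a non-negative integer")
        if self.charge not in (0, -1):
            raise ValueError(f"charge must be 0 or -1, got {self.charge}")

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementFormula") -> "ElementFormula":
        q = self.charge + other.charge
        if q < -1:
            raise ValueError("cannot combine two anions")
        return ElementFormula(
            self.c + other.c, self.h + other.h, self.n + other.n, self.o + other.o,
            charge=q, radical=self.radical ^ other.radical,
        )

    def __sub__(self, other: "ElementFormula") -> "ElementFormula":
        return subtract(self, other)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.c, self.h, self.n, self.o)

    def contains(self, other: "ElementFormula") -> bool:
        """Element-wise ``other <= self``."""
        return all(a >= b for a, b in zip(self.counts(), other.counts()))

    def is_empty(self) -> bool:
        return not any(self.counts())

    def as_anion(self, radical: bool | None = None) -> "ElementFormula":
        return replace(self, charge=-1, radical=self.radical if radical is None else radical)

    def as_neutral(self) -> "ElementFormula":
        return replace(self, charge=0)

    # -- formatting -------------------------------------------------------
    def __str__(self) -> str:
        return format_formula(self)

    def __format__(self, spec: str) -> str:  # pragma: no cover - convenience
        return format(str(self), spec)


NO3 = ElementFormula(n=1, o=3)
HNO3 = ElementFormula(h=1, n=1, o=3)
_REAGENT = {"NO3": NO3, "HNO3NO3": ElementFormula(h=1, n=2, o=6)}


def nitrate_adduct(neutral: ElementFormula, reagent: str = "NO3") -> ElementFormula:
    """Combined composition of the [M·NO3]− (or [M·HNO3NO3]−) cluster anion.

    The cluster keeps the electron parity of M: a peroxy radical gives an
    odd-electron adduct anion.
    """
    if reagent not in _REAGENT:
        raise ValueError(f"unknown reagent ion {reagent!r}")
    r = _REAGENT[reagent]
    return ElementFormula(
        neutral.c + r.c, neutral.h + r.h, neutral.n + r.n, neutral.o + r.o,
        charge=-1, radical=neutral.radical,
    )


_TOKEN = re.compile(r"([CHNO])(\d*)")


def _parse_counts(body: str) -> dict[str, int]:
    counts = {"C": 0, "H": 0, "N": 0, "O": 0}
    pos = 0
    for m in _TOKEN.finditer(body):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula fragment {body!r}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(body):
        raise ValueError(f"cannot parse formula fragment {body!r}")
    return counts


def parse_formula(text: str) -> ElementFormula:
    """Parse ``"C10H15NO11-"``, ``"C10H15O8·NO3-"`` (``.`` accepted for
    ``·``), with an optional ``•``/``*`` radical marker.

    Adduct spellings are normalized to the combined composition.
    """
    s = text.strip().replace(" ", "")
    radical = False
    for marker in ("•", "*"):
        if marker in s:
            radical = True
            s = s.replace(marker, "")
    charge = 0
    if s.endswith(("-", "−", "–")):
        charge = -1
        s = s[:-1]
    if not s:
        raise ValueError(f"empty formula string {text!r}")
    reagent = None
    for sep in ("·", "."):
        if sep in s:
            s, reagent = s.split(sep, 1)
            break
    counts = _parse_counts(s)
    f = ElementFormula(counts["C"], counts["H"], counts["N"], counts["O"],
                       charge=charge, radical=radical)
    if reagent is not None:
        if reagent not in _REAGENT:
            raise ValueError(f"unknown adduct reagent {reagent!r} in {text!r}")
        f = nitrate_adduct(replace(f, charge=0), reagent)
        if charge == 0:
            f = replace(f, charge=-1)  # adduct spelling implies the anion
    return f


def format_formula(f: ElementFormula) -> str:
    """Combined-composition string in fixed C, H, N, O order."""
    parts = []
    for sym, v in zip("CHNO", f.counts()):
        if v == 1:
            parts.append(sym)
        elif v > 1:
            parts.append(f"{sym}{v}")
    body = "".join(parts) or "(empty)"
    if f.radical:
        body += "•"
    if f.charge == -1:
        body += "-"
    return body


def monoisotopic_mass(f: ElementFormula, include_electron: bool = True) -> float:
    """Monoisotopic mass in Da; adds one electron mass for an anion when
    ``include_electron`` (the default convention)."""
    mass = f.c * MONOISOTOPIC["C"] + f.h * MONOISOTOPIC["H"] \
        + f.n * MONOISOTOPIC["N"] + f.o * MONOISOTOPIC["O"]
    if include_electron and f.charge == -1:
        mass += ELECTRON_MASS
    return mass


def mz(f: ElementFormula, include_electron: bool = True) -> float:
    """m/z of a singly charged anion; neutral species have no m/z."""
    if f.charge == 0:
        raise ValueError(f"neutral species {f} has no m/z")
    return monoisotopic_mass(f, include_electron=include_electron) / abs(f.charge)


def subtract(parent: ElementFormula, fragment: ElementFormula) -> ElementFormula:
    """Neutral-loss composition ``parent − fragment`` (charge 0).

    Raises ``ValueError`` if the fragment is not an element-wise
    sub-formula of the parent.
    """
    if not parent.contains(fragment):
        raise ValueError(f"{fragment} is not a sub-formula of {parent}")
    return ElementFormula(parent.c - fragment.c, parent.h - fragment.h,
                          parent.n - fragment.n, parent.o - fragment.o)


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed ppm deviation of *observed* from *theoretical* m/z."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(f: ElementFormula) -> float:
    """Ring-plus-double-bond equivalents, c − h/2 + n/2 + 1.

    Half-integer values are legitimate for radicals and adduct ions.
    """
    return f.c - f.h / 2.0 + f.n / 2.0 + 1.0


@dataclass(frozen=True)
class EnumerationBounds:
    """Element-count and RDBE bounds for formula enumeration.

    Defaults cover monoterpene monomers, dimers and their NO3−/HNO3NO3−
    adducts; at most two nitrogen atoms are allowed, reflecting the
    nitrate-CI adduct chemistry (analytes themselves are C/H/O only).
    """

    c: tuple[int, int] = (0, 25)
    h: tuple[int, int] = (0, 45)
    n: tuple[int, int] = (0, 2)
    o: tuple[int, int] = (0, 20)
    rdbe_range: tuple[float, float] = (-0.5, 20.0)
    tolerance_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        for lo, hi in (self.c, self.h, self.n, self.o):
            if lo < 0 or hi < lo:
                raise ValueError("invalid element bounds")


def _grid(bounds: EnumerationBounds) -> np.ndarray:
    axes = [np.arange(lo, hi + 1) for lo, hi in
            (bounds.c, bounds.h, bounds.n, bounds.o)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)


def enumerate_formulas(observed_mz: float,
                       bounds: EnumerationBounds | None = None,
                       include_electron: bool = True) -> list[ElementFormula]:
    """All anion formulas within the bounds whose m/z lies within
    ``bounds.tolerance_ppm`` of *observed_mz*.

    Sorted by |ppm error|, then ascending N, O, C, H counts — the same
    deterministic ordering used to break annotation ties.
    """
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    bounds = bounds or EnumerationBounds()
    grid = _grid(bounds)
    mass = grid @ _MASS_VECTOR
    if include_electron:
        mass = mass + ELECTRON_MASS
    ppm = 1e6 * (observed_mz - mass) / np.maximum(mass, 1e-12)
    d = grid.astype(float)
    rdbe_v = d[:, 0] - d[:, 1] / 2.0 + d[:, 2] / 2.0 + 1.0
    ok = (np.abs(ppm) <= bounds.tolerance_ppm) \
        & (rdbe_v >= bounds.rdbe_range[0]) & (rdbe_v <= bounds.rdbe_range[1]) \
        & (mass > 0)
    idx = np.nonzero(ok)[0]
    order = np.lexsort((grid[idx, 1], grid[idx, 0], grid[idx, 3],
                        grid[idx, 2], np.abs(ppm[idx])))
    return [ElementFormula(*(int(v) for v in grid[i]), charge=-1)
            for i in idx[order]]


def formulas_from_strings(texts: Iterable[str]) -> list[ElementFormula]:
    return [parse_formula(t) for t in texts]
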
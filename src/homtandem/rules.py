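"""Fragmentation-feasibility rules and candidate-structure elimination.

Candidate peroxy-radical and dimer structures are encoded as *feature
records* — radical-site class, quaternary-carbon flags, functional
groups — rather than molecular graphs, because those features are what
the collision-induced fragmentation chemistry discriminates:

* every peroxy radical loses O2 (the peroxy group itself);
* HNO3 loss marks closed-shell adducts, being rare for RO2 radicals;
* combined HNO3 + OH loss (H2NO4) after O2 loss needs a non-quaternary
  carbon adjacent to the alkyl-radical carbon;
* H2O loss points to a hydroperoxide, CO2 loss to a (peroxy) acid;
* OH elimination via intramolecular H-abstraction is impossible for a
  tertiary alkylperoxy radical;
* HO2 elimination needs a hydrogen on the carbon next to the RO2 site;
* CHO3 loss proceeds by radical recombination and needs the radical
  near a peroxy group (observed from O10 precursors as the cascade
  composition CHO5, i.e. O2 then CHO3);
* CH3O2 and C3H6O losses mark the gem-dimethyl quaternary carbon motif
  of bicyclic (α-pinene-type) skeletons;
* ROOR accretion products cleave at the peroxide bond with H-exchange,
  giving monomer-sized adduct ions.

A candidate survives elimination iff every observed neutral loss has at
least one applicable, feasible rule.  Growing the observed-loss set can
therefore only shrink the survivor set (monotonicity).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .formula import ElementFormula, HNO3, nitrate_adduct, parse_formula

__all__ = [
    "StructureRecord", "FragmentationRule", "RuleOutcome", "EliminationReport",
    "load_rules", "save_rules", "default_rules", "load_structures",
    "structure_library", "loss_feasible", "eliminate", "expand_scrambling",
    "dimer_cleavage_products", "infer_dimer_precursors", "feasible_losses",
]

SPECIES = ("RO2_radical", "closed_shell", "dimer")
SITE_CLASSES = ("primary", "secondary", "tertiary", "acylperoxy", "none")

O2 = ElementFormula(o=2)
_H = ElementFormula(h=1)
_O = ElementFormula(o=1)


@dataclass(frozen=True)
class StructureRecord:
    """Feature record for one candidate isomer.

    ``alpha_carbon_quaternary`` refers to the carbon adjacent to the
    alkyl-radical carbon *after O2 loss* (gates combined HNO3+OH loss);
    ``ro2_neighbor_quaternary`` refers to the carbon next to the intact
    RO2 site (gates HO2 elimination) — distinct positions on the carbon
    skeleton, hence two flags.
    """

    id: str
    species: str
    formula: ElementFormula
    system: str = ""
    ro2_site_class: str = "none"
    alpha_carbon_quaternary: bool = False
    ro2_neighbor_quaternary: bool = False
    has_hydroperoxide: bool = False
    has_peroxy_acid: bool = False
    has_carboxyl: bool = False
    has_carbonyl: bool = False
    radical_near_peroxy: bool = False
    gem_dimethyl_quaternary: bool = False
    scramble_sites: int = 0
    scramble_variants: tuple[Mapping, ...] = ()
    members: tuple["StructureRecord", ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"{self.id}: unknown species {self.species!r}")
        if self.ro2_site_class not in SITE_CLASSES:
            raise ValueError(f"{self.id}: unknown site class {self.ro2_site_class!r}")
        if self.species == "RO2_radical" and self.ro2_site_class == "none":
            raise ValueError(f"{self.id}: an RO2 radical needs a radical-site class")
        if self.species == "dimer" and len(self.members) != 2:
            raise ValueError(f"{self.id}: a dimer record needs exactly two members")
        if self.scramble_sites < 0:
            raise ValueError(f"{self.id}: scramble_sites must be >= 0")

    def feature_signature(self) -> tuple:
        """Structure-discriminating features only (id and scrambling
        bookkeeping excluded) — used to compare scrambling variants."""
        return (self.species, self.formula, self.ro2_site_class,
                self.alpha_carbon_quaternary, self.ro2_neighbor_quaternary,
                self.has_hydroperoxide, self.has_peroxy_acid, self.has_carboxyl,
                self.has_carbonyl, self.radical_near_peroxy,
                self.gem_dimethyl_quaternary)


@dataclass(frozen=True)
class FragmentationRule:
    """One declarative feasibility rule.

    ``losses`` are the single-step (precursor-minus-product) neutral
    compositions the rule explains; ``simulated_loss`` is the one the
    forward simulator applies.  ``dynamic`` marks the peroxide-cleavage
    rule, whose loss set depends on the dimer's member structures.
    """

    id: str
    losses: tuple[ElementFormula, ...]
    applies_to: frozenset[str]
    predicate: str
    explanation: str
    simulated_loss: ElementFormula | None = None
    dynamic: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "losses": [str(l) for l in self.losses],
            "applies_to": sorted(self.applies_to),
            "predicate": self.predicate,
            "explanation": self.explanation,
            "simulated_loss": None if self.simulated_loss is None
            else str(self.simulated_loss),
            "dynamic": self.dynamic,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FragmentationRule":
        return cls(
            id=d["id"],
            losses=tuple(parse_formula(l) for l in d["losses"]),
            applies_to=frozenset(d["applies_to"]),
            predicate=d["predicate"],
            explanation=d["explanation"],
            simulated_loss=None if d.get("simulated_loss") is None
            else parse_formula(d["simulated_loss"]),
            dynamic=bool(d.get("dynamic", False)),
        )


# -- predicates (pure functions of the feature record) ----------------------

def _any_peroxy_radical(r: StructureRecord) -> bool:
    return r.ro2_site_class != "none"


PREDICATES: dict[str, Callable[[StructureRecord], bool]] = {
    "any_peroxy_radical": _any_peroxy_radical,
    "always": lambda r: True,
    "alpha_not_quaternary": lambda r: not r.alpha_carbon_quaternary,
    "has_hydroperoxide": lambda r: r.has_hydroperoxide,
    "has_acid_group": lambda r: r.has_peroxy_acid or r.has_carboxyl,
    "not_tertiary": lambda r: r.ro2_site_class != "tertiary",
    "ro2_neighbor_not_quaternary": lambda r: not r.ro2_neighbor_quaternary,
    "radical_near_peroxy": lambda r: r.radical_near_peroxy,
    "gem_dimethyl": lambda r: r.gem_dimethyl_quaternary,
}


@dataclass(frozen=True)
class RuleOutcome:
    rule_id: str
    status: str  # feasible | infeasible | inapplicable
    explanation: str

    def __bool__(self) -> bool:
        return self.status == "feasible"


def loss_feasible(record: StructureRecord, rule: FragmentationRule,
                  loss: ElementFormula | None = None) -> RuleOutcome:
    """Evaluate one rule for one candidate.

    A species mismatch yields ``inapplicable`` (distinct from an
    infeasible rule).  The dynamic peroxide-cleavage rule additionally
    needs the observed *loss* to match one of the dimer's predicted
    cleavage complements.
    """
    if record.species not in rule.applies_to:
        return RuleOutcome(rule.id, "inapplicable",
                           f"{rule.id} does not apply to {record.species}")
    if rule.dynamic:
        if loss is None:
            return RuleOutcome(rule.id, "feasible", rule.explanation)
        complements = cleavage_complements(record)
        ok = any(loss.counts() == c.counts() for c in complements)
        status = "feasible" if ok else "infeasible"
        detail = rule.explanation if ok else (
            f"loss {loss} matches no RO-OR cleavage complement of {record.id}")
        return RuleOutcome(rule.id, status, detail)
    ok = PREDICATES[rule.predicate](record)
    return RuleOutcome(rule.id, "feasible" if ok else "infeasible",
                       rule.explanation if ok
                       else f"{rule.id} blocked: {rule.explanation}")


# -- default rule set (shipped as versioned JSON) ---------------------------

def load_rules(path: str | Path) -> list[FragmentationRule]:
    with open(path) as fh:
        payload = json.load(fh)
    return [FragmentationRule.from_dict(d) for d in payload["rules"]]


def save_rules(rules: Sequence[FragmentationRule], path: str | Path) -> None:
    payload = {"version": 1, "rules": [r.to_dict() for r in rules]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def default_rules() -> list[FragmentationRule]:
    with resources.files("homtandem.data").joinpath("rules.json").open() as fh:
        payload = json.load(fh)
    return [FragmentationRule.from_dict(d) for d in payload["rules"]]


# -- structure fixtures -----------------------------------------------------

_BOOL_FIELDS = ("alpha_carbon_quaternary", "ro2_neighbor_quaternary",
                "has_hydroperoxide", "has_peroxy_acid", "has_carboxyl",
                "has_carbonyl", "radical_near_peroxy", "gem_dimethyl_quaternary")


def _record_from_dict(d: Mapping, registry: Mapping[str, StructureRecord]
                      ) -> StructureRecord:
    kwargs = {
        "id": d["id"],
        "species": d["species"],
        "formula": parse_formula(d["formula"]),
        "system": d.get("system", ""),
        "ro2_site_class": d.get("ro2_site_class", "none"),
        "scramble_sites": int(d.get("scramble_sites", 0)),
        "scramble_variants": tuple(d.get("scramble_variants", [])),
        "notes": d.get("notes", ""),
    }
    for f in _BOOL_FIELDS:
        kwargs[f] = bool(d.get(f, False))
    member_ids = d.get("members", [])
    kwargs["members"] = tuple(registry[m] for m in member_ids)
    return StructureRecord(**kwargs)


def load_structures(path: str | Path) -> dict[str, StructureRecord]:
    """Load a structure-fixture JSON; dimer member ids are resolved
    against records defined earlier in the same file."""
    with open(path) as fh:
        payload = json.load(fh)
    registry: dict[str, StructureRecord] = {}
    for d in payload["structures"]:
        rec = _record_from_dict(d, registry)
        if rec.id in registry:
            raise ValueError(f"duplicate structure id {rec.id!r}")
        registry[rec.id] = rec
    return registry


def structure_library(name: str) -> dict[str, StructureRecord]:
    """Shipped fixture sets: ``limonene_o8``, ``limonene_o10``,
    ``limonene_pool``, ``alpha_pinene``."""
    ref = resources.files("homtandem.data").joinpath(f"{name}.json")
    if not ref.is_file():
        raise ValueError(f"unknown structure library {name!r}")
    with resources.as_file(ref) as path:
        return load_structures(path)


# -- elimination engine -----------------------------------------------------

@dataclass
class EliminationReport:
    surviving: list[str]
    eliminated: dict[str, list[dict]]
    traces: dict[str, list[dict]]
    ignored_losses: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"surviving": self.surviving, "eliminated": self.eliminated,
                "ignored_losses": self.ignored_losses, "traces": self.traces}

    def to_text(self) -> str:
        lines = [f"survivors: {', '.join(self.surviving) or '(none)'}"]
        for cid, reasons in self.eliminated.items():
            why = "; ".join(f"{r['loss']} ({r['rule']})" for r in reasons)
            lines.append(f"eliminated {cid}: {why}")
        if self.ignored_losses:
            lines.append("ignored losses (no known rule): "
                         + ", ".join(self.ignored_losses))
        return "\n".join(lines)


def _loss_key(f: ElementFormula) -> tuple:
    return f.counts()


def eliminate(candidates: Iterable[StructureRecord],
              observed_losses: Iterable[ElementFormula],
              rules: Sequence[FragmentationRule] | None = None,
              include_scrambling: bool = False) -> EliminationReport:
    """Keep candidates for which every observed loss has a feasible rule.

    Losses with no known rule (and matching no candidate's peroxide
    cleavage) are ignored with a warning entry.  With
    ``include_scrambling`` each candidate is expanded into its rapid
    H-shift scrambling variants first.
    """
    rules = list(rules) if rules is not None else default_rules()
    cands = list(candidates)
    if not cands:
        raise ValueError("candidate set must be non-empty")
    if include_scrambling:
        expanded: list[StructureRecord] = []
        for c in cands:
            expanded.extend(expand_scrambling(c))
        cands = expanded
    losses = list(observed_losses)

    static_index: dict[tuple, list[FragmentationRule]] = {}
    dynamic_rules = [r for r in rules if r.dynamic]
    for r in rules:
        for l in r.losses:
            static_index.setdefault(_loss_key(l), []).append(r)

    def known(loss: ElementFormula) -> bool:
        if _loss_key(loss) in static_index:
            return True
        return any(c.species == "dimer" and any(
            loss.counts() == comp.counts() for comp in cleavage_complements(c))
            for c in cands)

    ignored = [str(l) for l in losses if not known(l)]
    active = [l for l in losses if known(l)]

    surviving: list[str] = []
    eliminated: dict[str, list[dict]] = {}
    traces: dict[str, list[dict]] = {}
    for c in cands:
        trace: list[dict] = []
        blockers: list[dict] = []
        for loss in active:
            outcomes = [loss_feasible(c, r, loss)
                        for r in static_index.get(_loss_key(loss), [])]
            if c.species == "dimer":
                outcomes += [loss_feasible(c, r, loss) for r in dynamic_rules]
            for out in outcomes:
                trace.append({"loss": str(loss), "rule": out.rule_id,
                              "status": out.status,
                              "explanation": out.explanation})
            if not any(outcomes):
                blocker = next((o for o in outcomes if o.status == "infeasible"),
                               None)
                blockers.append({
                    "loss": str(loss),
                    "rule": blocker.rule_id if blocker is not None
                    else "no-applicable-rule",
                    "explanation": blocker.explanation if blocker is not None
                    else f"no rule applicable to {c.species} explains loss {loss}",
                })
        if blockers:
            eliminated[c.id] = blockers
        else:
            surviving.append(c.id)
        traces[c.id] = trace
    return EliminationReport(surviving=surviving, eliminated=eliminated,
                             traces=traces, ignored_losses=ignored)


def feasible_losses(record: StructureRecord,
                    rules: Sequence[FragmentationRule] | None = None
                    ) -> list[tuple[FragmentationRule, ElementFormula]]:
    """(rule, single-step loss) pairs the forward simulator applies.

    For dimers the peroxide-cleavage complements and the HNO3 loss are
    returned; for monomeric species, each applicable feasible static
    rule contributes its ``simulated_loss``.
    """
    rules = list(rules) if rules is not None else default_rules()
    out: list[tuple[FragmentationRule, ElementFormula]] = []
    adduct = nitrate_adduct(record.formula)
    for r in rules:
        if r.dynamic:
            if record.species == "dimer" and loss_feasible(record, r):
                for comp in cleavage_complements(record):
                    out.append((r, comp))
            continue
        if r.simulated_loss is None:
            continue
        if loss_feasible(record, r) and adduct.contains(r.simulated_loss):
            out.append((r, r.simulated_loss))
    return out


# -- scrambling -------------------------------------------------------------

def expand_scrambling(s: StructureRecord) -> list[StructureRecord]:
    """Rapid H-shift scrambling variants (labile H relocated among
    OOH/OO• sites), ids suffixed ``-scrb``.  The original record is
    always included; output size is bounded by ``scramble_sites + 1``.

    Variant feature overrides come from the fixture data when the
    relocated radical position is encoded in the fixture data; otherwise a
    single conservative variant with a non-quaternary alpha carbon is
    produced.
    """
    if s.scramble_sites < 1:
        return [s]
    overrides = list(s.scramble_variants)
    if not overrides:
        overrides = [{"alpha_carbon_quaternary": False}]
    overrides = overrides[: s.scramble_sites]
    variants = [s]
    for i, ov in enumerate(overrides):
        suffix = "-scrb" if len(overrides) == 1 else f"-scrb{i + 1}"
        variants.append(replace(s, id=s.id + suffix, scramble_sites=0,
                                scramble_variants=(), **dict(ov)))
    return variants


# -- dimer peroxide cleavage ------------------------------------------------

def dimer_cleavage_products(a: StructureRecord, b: StructureRecord
                            ) -> set[ElementFormula]:
    """Expected monomer-sized adduct ions from RO–OR bond cleavage with
    in-cage H-exchange.

    Each pathway turns one alkoxy side into a carbonyl (H-donor, −H) and
    the other into an alcohol (H-acceptor, +H).  An acylperoxy side
    carries no hydrogen at its radical carbon, so it cannot donate: the
    pathway in which it would lose H — and with it the partner's H-gain
    product — is unavailable, and only the acyl-side acid (+H) plus the
    partner-side carbonyl (−H) remain.
    """
    for r in (a, b):
        if r.species != "RO2_radical":
            raise ValueError(f"{r.id}: dimer cleavage needs RO2 radical members")

    def alkoxy(r: StructureRecord) -> ElementFormula:
        return r.formula - _O

    def h_loss(r: StructureRecord) -> ElementFormula:
        return nitrate_adduct((alkoxy(r) - _H).as_neutral())

    def h_gain(r: StructureRecord) -> ElementFormula:
        return nitrate_adduct(alkoxy(r) + _H)

    products: set[ElementFormula] = set()
    for donor, acceptor in ((a, b), (b, a)):
        if donor.ro2_site_class == "acylperoxy":
            continue  # no abstractable H at the acyl radical carbon
        products.add(h_loss(donor))
        products.add(h_gain(acceptor))
    return products


def cleavage_complements(record: StructureRecord) -> set[ElementFormula]:
    """Single-step neutral losses corresponding to the cleavage ions."""
    if record.species != "dimer":
        return set()
    adduct = nitrate_adduct(record.formula)
    out = set()
    for p in dimer_cleavage_products(*record.members):
        neutral = ElementFormula(adduct.c - p.c, adduct.h - p.h,
                                 adduct.n - p.n, adduct.o - p.o)
        out.add(neutral)
    return out


@dataclass(frozen=True)
class DimerPairHypothesis:
    pair: tuple[str, str]
    score: float
    predicted: tuple[str, ...]
    evidence: tuple[str, ...]
    oxygens: tuple[int, int] = (0, 0)

    @property
    def oxygen_asymmetry(self) -> int:
        return abs(self.oxygens[0] - self.oxygens[1])


def infer_dimer_precursors(dimer_formula: ElementFormula,
                           observed_products: Iterable[ElementFormula],
                           ro2_pool: Iterable[StructureRecord],
                           deprotonated_weight: float = 0.5
                           ) -> list[DimerPairHypothesis]:
    """Rank RO2 + RO2 precursor pairs of an ROOR dimer.

    Every pool pair with a.formula + b.formula − O2 equal to the dimer
    composition is scored by its predicted cleavage products found among
    the observed ions; a deprotonated counterpart ([fragment − HNO3]−,
    e.g. C10H13O7− for the C10H14O7 adduct) counts with reduced weight,
    since such ions can also arise from secondary fragmentation.  Ties
    are ranked by oxygen symmetry (|Oa − Ob|, smaller first).
    """
    observed = {f.counts() for f in observed_products}
    pool = [r for r in ro2_pool if r.species == "RO2_radical"]
    ranked: list[DimerPairHypothesis] = []
    for a, b in itertools.combinations_with_replacement(
            sorted(pool, key=lambda r: r.id), 2):
        combined = (a.formula.c + b.formula.c, a.formula.h + b.formula.h,
                    a.formula.n + b.formula.n, a.formula.o + b.formula.o - 2)
        if combined != dimer_formula.counts():
            continue
        predicted = sorted(dimer_cleavage_products(a, b), key=str)
        score = 0.0
        evidence = []
        for p in predicted:
            if p.counts() in observed:
                score += 1.0
                evidence.append(str(p))
            deprot = ElementFormula(p.c - HNO3.c, p.h - HNO3.h,
                                    p.n - HNO3.n, p.o - HNO3.o, charge=-1)
            if deprot.counts() in observed:
                score += deprotonated_weight
                evidence.append(str(deprot))
        ranked.append(DimerPairHypothesis(
            pair=(a.id, b.id), score=score,
            predicted=tuple(str(p) for p in predicted),
            evidence=tuple(evidence),
            oxygens=(a.formula.o, b.formula.o)))
    ranked.sort(key=lambda h: (-h.score, h.oxygen_asymmetry, h.pair))
    return ranked
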
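# Methods

## Scope and data model

The package analyzes product-ion spectra of [M·NO₃]⁻ (and
[M·HNO₃NO₃]⁻) clusters produced by nitrate chemical ionization of
monoterpene ozonolysis products: closed-shell monomers
(C₁₀H₁₄₋₁₆O₆₋₁₀), odd-electron peroxy radicals (C₁₀H₁₅O₆,₈,₁₀) and
ROOR accretion dimers (C₂₀H₃₀O₁₂,₁₄). All compositions are held as
C/H/N/O count vectors with a charge (0 or −1) and an odd-electron flag;
adducts are stored as the combined composition (C₁₀H₁₅O₈·NO₃⁻ ≡
C₁₀H₁₅NO₁₁⁻), which is what a high-resolution instrument actually
measures.

## Mass arithmetic and formula assignment

* Monoisotopic masses: IUPAC principal-isotope values; anion m/z adds
  one electron mass by default. Measured m/z values of these adducts
  are reproduced within the instrument's 5 ppm tolerance under this
  convention; matching is always tolerance-based (never
  exact-decimal), because printed experimental values mix calibration
  states.
* ppm error is signed and computed relative to the theoretical mass.
* Enumeration bounds: C 0–25, H 0–45, N 0–2, O 0–20,
  RDBE ∈ [−0.5, 20], tolerance 5 ppm. Analytes contain only C/H/O; the
  nitrogen allowance (≤ 2) accommodates the NO₃⁻/HNO₃NO₃⁻ reagent.
  The nitrogen rule is *not* enforced: adducts and odd-electron
  radical anions legitimately violate it. Candidates are ordered by
  |ppm|, then ascending N, O, C, H — a deterministic proxy for expert
  disambiguation; the same ordering breaks product-ion assignment
  ties.
* Product ions are assigned the best element-wise sub-formula of the
  precursor composition; the peaks matching NO₃⁻ and the precursor are
  tagged as reagent ion and precursor respectively, and unmatched
  peaks are kept as unassigned rather than dropped.
* Neutral losses are strictly single-step (precursor − product).
  Cascades such as O₂ followed by CHO₃ therefore appear as their
  combined composition (CHO₅); interpreting them mechanistically is
  the rule engine's job. Likewise, the combined HNO₃ + OH event is
  stored as H₂NO₄ — whether it is simultaneous or sequential is not
  decidable from the data and is left to the rules.

## Intensity processing

Relative intensities are base-peak normalized; the 0.1% relative
intensity floor is inclusive (rel ≥ floor survives), and the precursor
and NO₃⁻ peaks are never removed by the floor. The base peak is chosen
over all peaks, including the precursor. Centroids within 1 × 10⁻⁵ m/z
are merged (intensity-summed) on construction as a guard against
duplicated centroids.

## Similarity and clustering

Spectra are compared after annotation, as vectors keyed by product-ion
formula or by neutral-loss composition. Entries are square roots of
relative intensities (summed per key first); the NO₃⁻ ion is excluded
because its abundance reflects adduct binding strength rather than
analyte structure, and the precursor peak is excluded because it
dominates every low-energy spectrum and would saturate self-similarity
(switchable via `build_vector(include_precursor=True)`; the choice is
echoed in output metadata). Cosine similarity is computed over the
union key set (0 for an empty vector); clustering is complete-linkage
agglomerative on the distance 1 − s, computed with
`scipy.cluster.hierarchy.linkage` and cross-checked in the tests
against a naive O(n³) reference. Labels are sorted lexicographically
before linkage so tie-breaking is deterministic and
permutation-invariant; dendrograms are exported as Newick with branch
lengths equal to merge-height differences. The ≥ 0.2 similarity mask
is display-only and never feeds clustering.

## Fragmentation rules and elimination

Candidates are *feature records*, not molecular graphs: radical-site
class (primary/secondary/tertiary/acylperoxy), two distinct
quaternary-carbon flags, functional-group booleans, a scrambling-site
count. The features are exactly what the fragmentation chemistry
discriminates; full connectivity exists only in drawn structures, so
it enters the package as versioned JSON fixture data, never as code.
Two flags deserve emphasis because they refer to different skeleton
positions: `alpha_carbon_quaternary` is the carbon adjacent to the
alkyl radical *after O₂ loss* (gates combined HNO₃+OH loss), while
`ro2_neighbor_quaternary` is the carbon next to the intact RO₂ site
(gates HO₂ elimination). The shipped O₈ records set the latter true —
HO₂ loss is not part of the observed O₈ fragmentation — while the
non-tertiary O₁₀ records set it false.

A rule is a pure predicate over the record plus the loss compositions
it explains; each carries a mechanistic explanation string that
accompanies every verdict. Species mismatch yields "inapplicable",
distinct from "infeasible". Elimination keeps a candidate iff every
observed loss has at least one applicable feasible rule; a loss no
rule knows is ignored with a warning. Survivor sets are monotone
non-increasing in the observed-loss set (property-tested). "Most
plausible" is operationalized as "survives all feasibility checks" —
no probabilistic scoring, matching the qualitative character of the
underlying reasoning.

H-shift scrambling (rapid H exchange between –OOH and –OO• sites) is
modeled by `expand_scrambling`: variants (id suffixed `-scrb`) take
their feature overrides from the fixture data where the relocated
radical position is known (e.g. the route-B O₈ record whose variant is
feature-identical to A7); output size is bounded by
`scramble_sites + 1`. Scrambling variants are excluded from default
elimination runs and enabled by flag, since they extend rather than
replace the candidate set.

## Dimer cleavage and precursor inference

ROOR dimers (a.formula + b.formula − O₂, asserted at load time) cleave
at the peroxide bond into two alkoxy radicals that exchange a hydrogen
in-cage: per pathway one side loses H (carbonyl) and the other gains
it (alcohol), observed as monomer-sized NO₃⁻ adducts. An acylperoxy
side has no hydrogen at its radical carbon, cannot donate, and thus
removes the pathway in which it would lose H — suppressing both its
own H-loss product and the *partner's* H-gain product; the acyl side's
H-gain product is the corresponding acid. This reproduces the
observed contrast between the symmetric O₈+O₈ dimer (both exchange
products) and the acylperoxy-O₆+O₈ dimer (partner H-gain absent).

Precursor-pair inference enumerates all pool pairs consistent with the
dimer composition and scores each by predicted cleavage ions present
in the observed set. A deprotonated counterpart ([fragment − HNO₃]⁻)
counts with weight 0.5 (configurable), because such ions can also
arise from secondary fragmentation and are weaker evidence. Ties rank
by oxygen symmetry (|O_a − O_b| ascending), then pair id.

## Forward simulator

The simulator is the package's study-condition generator; its defaults
are fixed once and the tests run against them.

* NCE ladder 2/5/10 — the range used for these adducts.
* Ion-current shares at collision energy E: precursor exp(−kE) with
  k = 0.25 per NCE unit for monomers; dimers use k × 0.5, reflecting
  their stronger NO₃⁻ binding (slower declustering). Reagent share
  0.8 × (1 − exp(−kE)); the remainder is split over one product ion
  per feasible rule by a symmetric Dirichlet (α = 4). Any monotone
  model reproducing the qualitative trend — precursor dominant at low
  NCE, products and NO₃⁻ dominant at high NCE — would serve; this one
  makes the precursor's total-ion-current share strictly decreasing
  and the reagent's strictly increasing in NCE, which is what the
  property tests assert (base-peak-relative intensities saturate at 1
  and cannot be strictly monotone on both sides of the crossover).
* Mass error: Gaussian, sd 0.7 ppm, keeping ~99% of draws within the
  instrument's 2 ppm accuracy; sd 0 gives exact theoretical m/z, the
  basis of the forward–inverse identity tests.
* Total intensity is an arbitrary 10⁶ counts: absolute instrument
  scales (AGC target, injection time) have no simulated counterpart;
  only relative intensities are modeled.

What the simulator does *not* emulate: isotopologue peaks, in-source
fragmentation, chemical noise and contaminant peaks, co-isolated
precursors, multi-step fragmentation cascades within one scan, and
intensity saturation. Passing pipeline tests on simulated data
therefore demonstrate internal consistency (annotation inverts the
generator; elimination never kills the generating structure; related
spectra cluster), not instrument-level validation on real spectra.

## Problem sizes and numerics

Enumeration grids (≈ 75 000 compositions at the default bounds) and
sub-formula tables (≤ ~25 000 entries for a C₂₀ dimer precursor) are
vectorized with numpy; exhaustive nested-loop oracles back them in the
tests at the same bounds. The end-to-end soundness check simulates
117 spectra (39 fixture structures × 3 collision energies) — ample to
exercise every rule path while keeping the default suite in seconds.
Cosine values are clipped to [0, 1] against floating-point drift;
distance matrices are symmetrized before linkage. Degenerate inputs
have defined behavior throughout: empty vectors have similarity 0,
all-zero spectra refuse normalization, clustering and pairwise
similarity require ≥ 2 spectra, neutral species have no m/z, and an
empty enumeration result is a value, not an error (precursor
assignment, which needs a best candidate, raises with a
nearest-candidate diagnostic instead).

## Known limitations

* Feature records cannot express constraints the shipped flags do not
  encode; a new discriminating fragmentation channel requires a new
  rule plus a new fixture field.
* The elimination logic is qualitative: it cannot weigh partial
  intensities or rank survivors among themselves.
* Dimer cleavage predicts primary RO–OR products only; further
  fragmentation of cleavage products is captured solely through the
  reduced-weight deprotonated evidence in pair ranking.
* Multiply charged ions, elements beyond C/H/N/O, and isotope-pattern
  verification are out of scope.
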
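# homtandem

Structure inference for gas-phase peroxy radicals (RO₂) and their ROOR
accretion dimers from online NO₃⁻ chemical-ionization tandem mass
spectrometry.

Highly oxygenated organic molecules (HOMs) form within seconds when
monoterpene-derived RO₂ radicals autoxidize via intramolecular H-shifts
(RO₂ → R + –OOH, then R + O₂ → RO₂), and their low-volatility ROOR
dimers (RO₂ + RO₂ → ROOR + O₂) seed atmospheric new-particle formation.
Because NO₃⁻-CI Orbitrap MS/MS can fragment the [M·NO₃]⁻ cluster of a
short-lived radical in situ, the *neutral losses* between precursor and
product-ion formulas become structural probes: O₂ loss marks the peroxy
group, H₂O a hydroperoxide, CO₂ a (peroxy) acid, OH elimination is
impossible for tertiary alkylperoxy radicals, HO₂ elimination needs an
H on the carbon next to the RO₂ site, and so on. `homtandem` turns that
reasoning into a tested pipeline, for atmospheric chemists who want to
constrain which of many drawn isomers are compatible with an observed
MS/MS spectrum.

## What it computes

1. **Exact-mass annotation.** Anion m/z from standard monoisotopic
   masses (electron-inclusive, m/z = Σᵢ nᵢmᵢ + mₑ for z = −1), formula
   enumeration over C₀–₂₅H₀–₄₅N₀–₂O₀–₂₀ within a 5 ppm window with an
   RDBE filter (RDBE = C − H/2 + N/2 + 1), and sub-formula assignment of
   every product ion constrained by the precursor composition.
2. **Neutral-loss tables** — single-step precursor-minus-product
   compositions with summed relative intensities (0.1% floor).
3. **Spectral similarity and clustering.** Cosine similarity of
   √(relative intensity) vectors keyed by product-ion formula or by
   neutral-loss composition (NO₃⁻ and precursor excluded), and
   complete-linkage agglomerative clustering of the cosine distance
   1 − s, exported as Newick.
4. **Rule-based isomer elimination.** A declarative fragmentation-
   feasibility rule set over candidate feature records; a candidate
   survives iff every observed loss has a feasible rule.
5. **ROOR dimer inference.** Peroxide-bond cleavage with in-cage
   H-exchange predicts monomer-sized carbonyl (−H) and alcohol (+H)
   adduct ions; an acylperoxy side cannot donate H, which suppresses
   the partner's H-gain product. Candidate RO₂ + RO₂ precursor pairs
   are ranked by how many predicted cleavage ions are observed.
6. **A forward simulator** generating NO₃⁻-CI MS/MS spectra from
   structure records (precursor declustering vs. collision energy,
   Gaussian ppm mass error, Dirichlet product intensities), so the
   whole pipeline is testable without instrument data.

## Worked example

```python
from homtandem import (ElementFormula, mz, parse_formula, ppm_error,
                       assign_precursor, annotate_products, loss_table,
                       eliminate, structure_library, simulate_spectrum,
                       SimulationConfig)

# exact mass of the O8 radical adduct C10H15O8·NO3- (= C10H15NO11-)
adduct = parse_formula("C10H15O8·NO3-")
print(f"{mz(adduct):.4f}  ({ppm_error(mz(adduct), 325.0644):+.1f} ppm vs 325.0644)")

# simulate its spectrum noiselessly, annotate, and read off the losses
o8 = structure_library("limonene_o8")
s = simulate_spectrum(o8["A2"], nce=5, cfg=SimulationConfig(mass_error_ppm_sd=0))
parent = assign_precursor(s)
table = loss_table(annotate_products(s, parent))
print(sorted(table.loss))

# which of the fourteen candidate O8 isomers survive those losses?
losses = [parse_formula(t) for t in table.loss]
print(sorted(eliminate(o8.values(), losses).surviving))
```

prints

```
325.0651  (-2.0 ppm vs 325.0644)
['CO2', 'H2NO4', 'H2O', 'HO', 'O2']
['A1', 'A2', 'A7', 'B1', 'B2']
```

i.e. the measured precursor m/z sits 2 ppm below the theoretical
adduct mass, well within the instrument tolerance; the annotated
losses are O₂, combined
HNO₃+OH (H₂NO₄), H₂O, CO₂ and OH; and exactly the five isomers whose
site chemistry permits all of those losses survive — the A/B 1, A/B 2
and A7 shortlist.

The same stages are available from the shell:

```bash
homtandem simulate --fixtures limonene_o8 --out spectra.mgf --truth truth.csv --seed 1
homtandem annotate --in spectra.mgf --out annotated.csv
homtandem infer-structures --in spectra.mgf --candidates limonene_o8 --out report.json
homtandem cluster --in spectra.mgf --mode neutral_losses --out tree.nwk
```

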
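"""Fragmentation-feasibility rules, candidate elimination, dimer inference."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from homtandem.formula import ElementFormula, parse_formula
from homtandem.rules import (FragmentationRule, StructureRecord, default_rules,
                             dimer_cleavage_products, eliminate,
                             expand_scrambling, infer_dimer_precursors,
                             load_rules, loss_feasible, save_rules)

RULES = {r.id: r for r in default_rules()}


def loss(text):
    return parse_formula(text)


O8_OBSERVED_LOSSES = [loss(s) for s in ("O2", "H2NO4", "H2O", "CO2", "HO")]
O10_OBSERVED_LOSSES = [loss(s) for s in ("O2", "HO", "HO2", "CHO5")]


class TestLossFeasible:
    def test_every_ro2_can_lose_o2(self, o8_library):
        for record in o8_library.values():
            assert loss_feasible(record, RULES["R-O2"])

    def test_tertiary_blocks_oh_elimination(self, o8_library):
        out = loss_feasible(o8_library["A3"], RULES["R-OH"])
        assert out.status == "infeasible"
        assert "tertiary" in out.explanation

    def test_quaternary_alpha_blocks_combined_hno3_oh(self, o8_library):
        out = loss_feasible(o8_library["A4"], RULES["R-HNO3-OH"])
        assert out.status == "infeasible"

    def test_species_mismatch_is_inapplicable_not_false(self, o8_library):
        out = loss_feasible(o8_library["A2"], RULES["R-HNO3"])
        assert out.status == "inapplicable"

    def test_outcomes_carry_explanations(self, o8_library):
        for rule in RULES.values():
            out = loss_feasible(o8_library["A2"], rule)
            assert out.explanation


class TestEliminate:
    def test_o8_survivors(self, o8_library):
        report = eliminate(o8_library.values(), O8_OBSERVED_LOSSES)
        assert set(report.surviving) == {"A1", "A2", "B1", "B2", "A7"}

    def test_o8_elimination_traces(self, o8_library):
        report = eliminate(o8_library.values(), O8_OBSERVED_LOSSES)
        for cid in ("A4", "A5", "A6", "B4", "B5", "B6", "B7"):
            assert any(r["rule"] == "R-HNO3-OH" for r in report.eliminated[cid])
        for cid in ("A3", "B3"):
            assert any(r["rule"] == "R-OH" for r in report.eliminated[cid])

    def test_o10_survivors(self, o10_library):
        report = eliminate(o10_library.values(), O10_OBSERVED_LOSSES)
        assert set(report.surviving) == {"A1-1", "B1-1", "A2-1", "B2-1", "A7-2"}

    def test_o10_cho3_trace(self, o10_library):
        report = eliminate(o10_library.values(), O10_OBSERVED_LOSSES)
        for cid in ("A1-2", "B1-2"):
            assert any(r["rule"] == "R-CHO3" for r in report.eliminated[cid])

    def test_empty_losses_keep_everything(self, o8_library):
        report = eliminate(o8_library.values(), [])
        assert set(report.surviving) == set(o8_library)

    def test_unknown_loss_ignored_with_warning(self, o8_library):
        weird = ElementFormula(c=5, h=1)
        report = eliminate(o8_library.values(), [weird])
        assert report.ignored_losses == [str(weird)]
        assert set(report.surviving) == set(o8_library)

    def test_partition_is_exact(self, o8_library):
        report = eliminate(o8_library.values(), O8_OBSERVED_LOSSES)
        assert set(report.surviving) | set(report.eliminated) == set(o8_library)
        assert not set(report.surviving) & set(report.eliminated)

    def test_scrambling_rescues_route_b_variants(self, o8_library):
        report = eliminate(o8_library.values(), O8_OBSERVED_LOSSES,
                           include_scrambling=True)
        assert "B7-scrb" in report.surviving
        assert "B3-scrb" in report.surviving
        assert "B7" not in report.surviving

    @given(subset_idx=st.sets(st.sampled_from(range(len(O8_OBSERVED_LOSSES))),
                              max_size=5),
           extra_idx=st.sampled_from(range(len(O8_OBSERVED_LOSSES))))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_observed_losses(self, o8_library, subset_idx,
                                         extra_idx):
        subset = [O8_OBSERVED_LOSSES[i] for i in sorted(subset_idx)]
        grown = subset + [O8_OBSERVED_LOSSES[extra_idx]]
        before = set(eliminate(o8_library.values(), subset).surviving)
        after = set(eliminate(o8_library.values(), grown).surviving)
        assert after <= before


class TestScrambling:
    def test_no_sites_returns_original_only(self, o8_library):
        assert expand_scrambling(o8_library["A1"]) == [o8_library["A1"]]

    def test_b7_variant_equivalent_to_a7(self, o8_library):
        variants = expand_scrambling(o8_library["B7"])
        scrb = next(v for v in variants if v.id == "B7-scrb")
        assert scrb.feature_signature() == o8_library["A7"].feature_signature()

    @pytest.mark.parametrize("structure_id", ["B1", "B3", "B7", "A1-1"])
    def test_output_bounded_by_sites(self, structure_id, o8_library,
                                     o10_library):
        record = (o8_library | o10_library)[structure_id]
        assert len(expand_scrambling(record)) <= record.scramble_sites + 1


class TestDimerCleavage:
    def test_symmetric_o8_pair_gives_both_exchange_products(self, pool_library):
        o8 = pool_library["lim-O8"]
        products = dimer_cleavage_products(o8, o8)
        assert products == {parse_formula("C10H14NO10-"),
                            parse_formula("C10H16NO10-")}

    def test_acylperoxy_side_suppresses_partner_h_gain(self, pool_library):
        products = dimer_cleavage_products(pool_library["lim-O6-acyl"],
                                           pool_library["lim-O8"])
        assert parse_formula("C10H14NO10-") in products
        assert parse_formula("C10H16NO10-") not in products
        # the acyl side can only accept H, giving the O6 acid adduct
        assert parse_formula("C10H16NO8-") in products

    def test_argument_order_irrelevant(self, pool_library):
        a, b = pool_library["lim-O6-acyl"], pool_library["lim-O8"]
        assert dimer_cleavage_products(a, b) == dimer_cleavage_products(b, a)

    def test_non_radical_input_rejected(self, pool_library):
        with pytest.raises(ValueError, match="RO2 radical"):
            dimer_cleavage_products(pool_library["lim-C10H16O8"],
                                    pool_library["lim-O8"])

    def test_dimer_formula_arithmetic(self, pool_library, pinene_library):
        for lib in (pool_library, pinene_library):
            for record in lib.values():
                if record.species != "dimer":
                    continue
                a, b = record.members
                combined = ElementFormula(
                    a.formula.c + b.formula.c, a.formula.h + b.formula.h,
                    a.formula.n + b.formula.n, a.formula.o + b.formula.o - 2)
                assert combined.counts() == record.formula.counts()


class TestInferDimerPrecursors:
    def test_limonene_o14_prefers_o8_pair(self, pool_library):
        observed = [parse_formula(s) for s in
                    ("C10H14NO10-", "C10H16NO10-", "C10H13O7-")]
        ranking = infer_dimer_precursors(parse_formula("C20H30O14"), observed,
                                         pool_library.values())
        assert ranking[0].pair == ("lim-O8", "lim-O8")
        assert ranking[0].score > ranking[1].score

    def test_pinene_o12_prefers_o4_o10_pair(self, pinene_library):
        observed = [parse_formula("C10H16NO12-"), parse_formula("C10H15O9-")]
        ranking = infer_dimer_precursors(parse_formula("C20H30O12"), observed,
                                         pinene_library.values())
        assert set(ranking[0].pair) == {"ap-O4", "ap-O10"}

    def test_no_evidence_ties_at_zero(self, pool_library):
        ranking = infer_dimer_precursors(parse_formula("C20H30O14"), [],
                                         pool_library.values())
        assert {h.score for h in ranking} == {0.0}
        # symmetric O8+O8 outranks O6+O10 on oxygen symmetry
        assert ranking[0].pair == ("lim-O8", "lim-O8")

    def test_impossible_dimer_gives_empty_ranking(self, pool_library):
        ranking = infer_dimer_precursors(parse_formula("C20H30O9"), [],
                                         pool_library.values())
        assert ranking == []


class TestRuleSerialization:
    def test_round_trip_through_json(self, tmp_path):
        rules = default_rules()
        path = tmp_path / "rules.json"
        save_rules(rules, path)
        assert load_rules(path) == rules

    def test_every_rule_has_explanation_and_species(self):
        for rule in default_rules():
            assert rule.explanation.strip()
            assert rule.applies_to

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError, match="radical-site class"):
            StructureRecord(id="x", species="RO2_radical",
                            formula=parse_formula("C10H15O8"))
        with pytest.raises(ValueError, match="two members"):
            StructureRecord(id="d", species="dimer",
                            formula=parse_formula("C20H30O14"))
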
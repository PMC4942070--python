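import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abdesign import (
    MTDOutcome,
    OutcomeKind,
    Stage1Action,
    Stage2Action,
    ToxScenario,
    enumerate_pathways,
    pathway_probability,
    stage1_decision,
    stage2_decision,
    validate_design,
)
from _oracle import brute_force_pathways, pathwayset_as_dict
from conftest import EXAMPLES, quiet_design, quiet_scenario


class TestValidation:
    def test_classical_3plus3_is_valid(self):
        d = validate_design(3, 3, 1, 1, 1, False)
        assert (d.A, d.B, d.C, d.D, d.E) == (3, 3, 1, 1, 1)
        assert not d.allow_deescalation

    def test_2plus4_with_deescalation_is_valid(self):
        d = validate_design(2, 4, 1, 1, 2, True)
        assert d.max_per_dose == 6 and d.allow_deescalation

    @pytest.mark.parametrize(
        "args",
        [
            (3, 3, 2, 1, 1),  # C > D
            (3, 3, 1, 4, 1),  # D > A
            (3, 3, 0, 1, 1),  # C < 1
            (3, 3, 1, 1, 7),  # E > A+B
            (3, 3, 1, 1, -1),  # E < 0
            (0, 3, 1, 1, 1),  # A < 1
            (3, 0, 1, 1, 1),  # B < 1
        ],
    )
    def test_invariant_violations_rejected(self, args):
        with pytest.raises(ValueError):
            validate_design(*args)

    def test_non_integer_parameters_rejected(self):
        with pytest.raises(TypeError):
            validate_design(3.0, 3, 1, 1, 1)

    def test_e_below_c_warns_but_is_legal(self):
        with pytest.warns(UserWarning, match="E=0 < C=1"):
            validate_design(3, 3, 1, 1, 0)

    def test_nonmonotone_scenario_warns(self):
        with pytest.warns(UserWarning, match="not monotone"):
            ToxScenario([0.3, 0.1])

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_out_of_range_probability_rejected(self, bad):
        with pytest.raises(ValueError):
            ToxScenario([0.1, bad])


class TestDecisionRules:
    @pytest.mark.parametrize(
        "x,expected",
        [(0, Stage1Action.ESCALATE), (1, Stage1Action.EXPAND),
         (2, Stage1Action.HALT), (3, Stage1Action.HALT)],
    )
    def test_3plus3_stage1(self, design_33, x, expected):
        assert stage1_decision(design_33, x) is expected

    def test_stage1_rejects_out_of_range(self, design_33):
        with pytest.raises(ValueError):
            stage1_decision(design_33, 4)
        with pytest.raises(ValueError):
            stage1_decision(design_33, -1)

    @pytest.mark.parametrize(
        "y,expected", [(1, Stage2Action.ESCALATE), (2, Stage2Action.HALT)]
    )
    def test_3plus3_stage2(self, design_33, y, expected):
        assert stage2_decision(design_33, y) is expected

    @pytest.mark.parametrize(
        "y,expected",
        [(1, Stage2Action.ESCALATE), (2, Stage2Action.ESCALATE), (3, Stage2Action.HALT)],
    )
    def test_2plus4_stage2_escalates_up_to_two_of_six(self, design_24_deesc, y, expected):
        assert stage2_decision(design_24_deesc, y) is expected

    def test_stage2_rejects_count_below_stage1_minimum(self, design_33):
        with pytest.raises(ValueError):
            stage2_decision(design_33, 0)


class TestDegenerateScenarios:
    def test_zero_toxicity_gives_single_full_escalation_pathway(self, design_33):
        ps = enumerate_pathways(design_33, ToxScenario([0.0] * 4))
        assert len(ps) >= 1
        certain = [p for p in ps if p.probability == 1.0]
        assert len(certain) == 1
        pw = certain[0]
        assert pw.n_total == 12 and pw.dlt_total == 0
        assert pw.mtd.kind is OutcomeKind.ALL_TOLERATED
        assert [(c.dose, c.size, c.dlts) for c in pw.cohorts] == [
            (1, 3, 0), (2, 3, 0), (3, 3, 0), (4, 3, 0)
        ]

    def test_certain_toxicity_stops_at_first_dose(self, design_33):
        ps = enumerate_pathways(design_33, ToxScenario([1.0]))
        certain = [p for p in ps if p.probability == 1.0]
        assert len(certain) == 1
        pw = certain[0]
        assert pw.n_total == 3 and pw.dlt_total == 3
        assert pw.mtd.kind is OutcomeKind.NONE_TOO_TOXIC


class TestPathwayProbability:
    def test_single_cohort_half_probability(self):
        ps = enumerate_pathways(quiet_design(3, 3, 1, 1, 1), quiet_scenario([0.5]))
        by_first = {pw.cohorts[0].dlts: pw for pw in ps if len(pw.cohorts) == 1}
        assert by_first[0].probability == pytest.approx(0.125)  # (1/2)^3

    def test_binomial_term_for_one_dlt(self):
        ps = enumerate_pathways(quiet_design(3, 3, 1, 1, 1), quiet_scenario([0.33]))
        # the x=1 branches all start with the same stage-1 factor
        for pw in ps:
            if pw.cohorts[0].dlts == 1 and len(pw.cohorts) == 1:
                pytest.fail("x=1 must expand, never terminate alone")
        recomputed = 3 * 0.33 * 0.67**2
        assert recomputed == pytest.approx(0.444411)

    def test_example_pathway_product_frozen(self, example_pathways):
        # 0/3 at dose 1, 0/3 at dose 2, 2/3 at dose 3 under Example I
        target = ((1, 3, 0), (2, 3, 0), (3, 3, 2))
        matches = [
            pw for pw in example_pathways["I"]
            if tuple((c.dose, c.size, c.dlts) for c in pw.cohorts) == target
        ]
        assert len(matches) == 1
        # 0.95^3 * 0.90^3 * C(3,2) 0.33^2 0.67, multiplied out by hand
        assert matches[0].probability == pytest.approx(0.136811398197375, rel=1e-12)

    def test_recomputation_matches_stored_probability(self, example_pathways):
        for name, ps in example_pathways.items():
            for pw in ps:
                assert pathway_probability(pw, ps.scenario) == pytest.approx(
                    pw.probability, rel=1e-12
                )


class TestMTDOutcome:
    def test_selected_requires_dose(self):
        with pytest.raises(ValueError):
            MTDOutcome(OutcomeKind.SELECTED)
        with pytest.raises(ValueError):
            MTDOutcome(OutcomeKind.NONE_TOO_TOXIC, dose=2)

    def test_halt_above_dose_one_selects_previous(self, example_pathways):
        for pw in example_pathways["I"]:
            halted = pw.cohorts[-1].dose
            if pw.mtd.kind is OutcomeKind.SELECTED:
                assert pw.mtd.dose == halted - 1
            elif pw.mtd.kind is OutcomeKind.NONE_TOO_TOXIC:
                assert halted == 1

    def test_deescalation_mtd_always_has_full_cohort(self, example_pathways):
        design = EXAMPLES["III"][0]
        for pw in example_pathways["III"]:
            if pw.mtd.kind is OutcomeKind.SELECTED:
                j = pw.mtd.dose
                assert pw.patients_per_dose[j - 1] == design.max_per_dose
                assert pw.dlts_per_dose[j - 1] <= design.E


design_strategy = st.tuples(
    st.integers(1, 3), st.integers(1, 3)
).flatmap(
    lambda ab: st.tuples(
        st.just(ab[0]),
        st.just(ab[1]),
        st.integers(1, ab[0]),
        st.integers(1, ab[0]),
        st.integers(0, ab[0] + ab[1]),
        st.booleans(),
    ).filter(lambda t: t[2] <= t[3])
)

scenario_strategy = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=3
)


@settings(max_examples=60, deadline=None)
@given(design=design_strategy, probs=scenario_strategy)
def test_enumeration_matches_independent_oracle(design, probs):
    """Small-instance equivalence with a separately coded exhaustive walk."""
    A, B, C, D, E, deesc = design
    ps = enumerate_pathways(quiet_design(A, B, C, D, E, deesc), quiet_scenario(probs))
    got = pathwayset_as_dict(ps)
    expected = brute_force_pathways(A, B, C, D, E, deesc, list(probs))
    assert got.keys() == expected.keys()
    for key, (prob, outcome) in expected.items():
        assert got[key][1] == outcome
        assert got[key][0] == pytest.approx(prob, abs=1e-14)


@settings(max_examples=60, deadline=None)
@given(design=design_strategy, probs=scenario_strategy)
def test_enumeration_invariants(design, probs):
    """Probability conservation, the per-dose patient cap, and determinism."""
    A, B, C, D, E, deesc = design
    d = quiet_design(A, B, C, D, E, deesc)
    sc = quiet_scenario(probs)
    ps = enumerate_pathways(d, sc)
    assert math.fsum(pw.probability for pw in ps) == pytest.approx(1.0, abs=1e-12)
    seen = set()
    for pw in ps:
        key = tuple((c.dose, c.size, c.dlts) for c in pw.cohorts)
        assert key not in seen  # pathways pairwise distinct
        seen.add(key)
        assert max(pw.patients_per_dose) <= A + B
        assert pw.n_total == sum(c.size for c in pw.cohorts)
        assert pw.dlt_total == sum(c.dlts for c in pw.cohorts) <= pw.n_total
    again = enumerate_pathways(d, sc)
    assert pathwayset_as_dict(again) == pathwayset_as_dict(ps)
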
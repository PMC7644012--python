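"""Rule firing, aggregation, defuzzification and the end-to-end classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doubleyolk import (EggRecord, FuzzyDegrees, RuleBase, aggregate_rss,
                        classify_egg, defuzzify_centroid, fire_rules,
                        worked_example_fixture)

from _oracle import classify_literal

WORKED_GI = FuzzyDegrees(0.0, 0.5, 0.5)
WORKED_WI = FuzzyDegrees(0.25, 0.75, 0.0)
WORKED_STRENGTHS = (0.0, 0.0, 0.0, 0.25, 0.50, 0.0, 0.25, 0.50, 0.0)


class TestFireRules:
    def test_worked_example_strengths(self):
        assert fire_rules(WORKED_GI, WORKED_WI) == pytest.approx(WORKED_STRENGTHS, abs=1e-12)

    def test_zero_gi_silences_all_rules(self):
        assert fire_rules(FuzzyDegrees(0, 0, 0), FuzzyDegrees(1, 0.5, 0.2)).sum() == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    def test_matches_double_loop_brute_force(self, vals):
        gi, wi = FuzzyDegrees(*vals[:3]), FuzzyDegrees(*vals[3:])
        got = fire_rules(gi, wi)
        expected = [min(gi[i], wi[j]) for i in range(3) for j in range(3)]
        assert got == pytest.approx(expected, abs=0)

    def test_out_of_range_degrees_rejected(self):
        with pytest.raises(ValueError):
            fire_rules(FuzzyDegrees(0, 0.5, 1.5), FuzzyDegrees(0, 0, 0))


class TestAggregateRss:
    def test_worked_example_masses(self):
        m_s, m_d = aggregate_rss(WORKED_STRENGTHS)
        assert m_s == pytest.approx(np.sqrt(0.25**2 + 0.50**2 + 0.25**2), abs=1e-12)
        assert round(m_s, 3) == 0.612
        assert m_d == pytest.approx(0.50, abs=1e-12)

    def test_no_fired_rules(self):
        assert aggregate_rss([0.0] * 9) == (0.0, 0.0)

    def test_singleton_double_rule(self):
        strengths = [0.0] * 9
        strengths[8] = 1.0  # GI high x WI high concludes DY
        assert aggregate_rss(strengths) == (0.0, 1.0)

    def test_default_grid_partition(self):
        """Single-class rules are {1,2,4,5,7}; double-class {3,6,8,9} (1-based)."""
        flat = RuleBase().flat
        assert list(np.flatnonzero(flat == 0) + 1) == [1, 2, 4, 5, 7]
        assert list(np.flatnonzero(flat == 1) + 1) == [3, 6, 8, 9]


class TestDefuzzify:
    def test_worked_example_truth(self):
        m_s, m_d = aggregate_rss(WORKED_STRENGTHS)
        truth, degenerate = defuzzify_centroid(m_s, m_d)
        assert round(truth, 3) == 0.449
        assert not degenerate

    @pytest.mark.parametrize("m_s, m_d, expected", [
        (0.0, 0.7, 1.0),
        (0.3, 0.0, 0.0),
        (0.4, 0.4, 0.5),
    ])
    def test_mass_limits(self, m_s, m_d, expected):
        truth, _ = defuzzify_centroid(m_s, m_d)
        assert truth == pytest.approx(expected, abs=1e-12)

    def test_degenerate_flagged_not_raised(self):
        truth, degenerate = defuzzify_centroid(0.0, 0.0)
        assert truth == 0.0 and degenerate


class TestClassifyEgg:
    def test_worked_example_full_pipeline(self, worked_clf):
        res = worked_clf.classify(worked_example_fixture())
        assert res.truth_value == pytest.approx(0.449, abs=5e-4)
        assert res.label == "SY"

    def test_saturated_high_corner_is_double(self, worked_clf):
        res = worked_clf.classify_value(weight=100.0, ratio=1.60)
        assert res.truth_value == 1.0
        assert res.label == "DY"
        assert res.rule_strengths[8] == 1.0  # only the high/high rule fires

    def test_saturated_low_corner_is_single(self, worked_clf):
        res = worked_clf.classify_value(weight=55.0, ratio=1.20)
        assert res.truth_value == 0.0
        assert res.label == "SY"
        assert res.rule_strengths[0] == 1.0

    def test_invalid_egg_rejected(self, worked_clf):
        with pytest.raises(ValueError):
            worked_clf.classify(EggRecord(weight=-5.0, ratio=1.4))
        with pytest.raises(ValueError):
            worked_clf.classify(EggRecord(weight=60.0, ratio=0.8))

    def test_threshold_tie_goes_to_double(self, worked_clf):
        """At truth == threshold the double-yolk class is the closed set."""
        truth = worked_clf.classify(worked_example_fixture()).truth_value
        res = classify_egg(worked_example_fixture(), worked_clf.gi_set,
                           worked_clf.wi_set, threshold=truth)
        assert res.label == "DY"


class TestEndToEndOracle:
    def test_thousand_random_inputs_match_literal_transcription(self, worked_clf):
        """The classifier equals a naive step-by-step transcription to 1e-12."""
        rng = np.random.default_rng(42)
        ratios = rng.uniform(1.0, 1.8, 1000)
        weights = rng.uniform(45.0, 110.0, 1000)
        gi_anchors = worked_clf.gi_set.anchors
        wi_anchors = worked_clf.wi_set.anchors
        for r, w in zip(ratios, weights):
            res = worked_clf.classify_value(weight=w, ratio=r)
            lit = classify_literal(r, w, gi_anchors, wi_anchors)
            assert res.truth_value == pytest.approx(lit["truth"], abs=1e-12)
            assert res.mass_single == pytest.approx(lit["mass_single"], abs=1e-12)
            assert res.mass_double == pytest.approx(lit["mass_double"], abs=1e-12)
            assert list(res.rule_strengths) == pytest.approx(lit["strengths"], abs=1e-12)
            assert res.label == lit["label"]


class TestProperties:
    def test_truth_always_in_unit_interval(self, case3_clf):
        rng = np.random.default_rng(7)
        for r, w in zip(rng.uniform(1.0, 2.0, 300), rng.uniform(41, 120, 300)):
            assert 0.0 <= case3_clf.truth_value(w, r) <= 1.0

    def test_monotone_in_weight_at_pure_shape_categories(self, case3_clf):
        """At inputs whose GI degree sits wholly in one category, the truth
        value is non-decreasing in weight (single rule row active)."""
        weights = np.linspace(45, 110, 261)
        for r in (1.05, 1.40, 1.70):  # saturated low / exact medium / saturated high
            t = [case3_clf.truth_value(w, r) for w in weights]
            assert all(b >= a - 1e-12 for a, b in zip(t, t[1:]))
        ratios = np.linspace(1.0, 1.9, 181)
        for w in (50.0, 75.0, 100.0):  # pure WI categories
            t = [case3_clf.truth_value(w, r) for r in ratios]
            assert all(b >= a - 1e-12 for a, b in zip(t, t[1:]))

    def test_rss_aggregation_is_not_globally_monotone(self, case3_clf):
        """Known counterexample: when an input's membership splits across two
        categories whose rules conclude the same class, the min operator caps
        both strengths and their root-sum-square falls short of the unsplit
        mass, so the truth value can dip as the egg gets more elongated."""
        t_pure = case3_clf.truth_value(83.0, 1.30)   # GI wholly low: R3 = 0.8
        t_split = case3_clf.truth_value(83.0, 1.35)  # GI split: R3 = R6 = 0.5
        assert t_pure == pytest.approx(0.8, abs=1e-12)
        assert t_split == pytest.approx(np.sqrt(0.5) / (np.sqrt(0.08) + np.sqrt(0.5)),
                                        abs=1e-12)
        assert t_split < t_pure  # more elongated, yet lower double-yolk truth

    def test_label_swap_maps_truth_to_complement(self, worked_clf):
        """Flipping every rule conclusion sends truth t -> 1 - t."""
        flipped = RuleBase().inverted()
        rng = np.random.default_rng(3)
        for r, w in zip(rng.uniform(1.0, 1.8, 200), rng.uniform(45, 110, 200)):
            egg = EggRecord(weight=w, ratio=r)
            t = classify_egg(egg, worked_clf.gi_set, worked_clf.wi_set).truth_value
            t_flip = classify_egg(egg, worked_clf.gi_set, worked_clf.wi_set,
                                  rules=flipped).truth_value
            assert t_flip == pytest.approx(1.0 - t, abs=1e-12)


class TestRuleBaseValidation:
    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            RuleBase(((0, 0), (0, 0), (0, 1)))
        with pytest.raises(ValueError):
            RuleBase(((0, 0, 2), (0, 0, 1), (0, 1, 1)))
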
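import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import varcal as vc
from varcal.evidence_model import EvidenceCounts
from varcal.local_calibration import LocalCalibrationCurve


def make_curve(grid, lr, prior=0.5):
    lr = np.asarray(lr, dtype=float)
    odds = lr * prior / (1 - prior)
    post = odds / (1 + odds)
    n = len(lr)
    return LocalCalibrationCurve(
        grid=np.asarray(grid, dtype=float), posterior_test=post, lr_plus=lr,
        window_halfwidth=np.ones(n), window_count=np.full(n, 50),
        test_prior=prior, epsilon=1.0)


class TestLevelRequirements:
    def test_roots_of_c(self):
        reqs = vc.level_requirements(350.0)
        assert reqs["supporting"] == pytest.approx(350 ** 0.125)
        assert reqs["moderate"] == pytest.approx(350 ** 0.25)
        assert reqs["strong"] == pytest.approx(math.sqrt(350))
        assert reqs["very_strong"] == 350.0

    def test_printed_rounded_values_for_c_350(self):
        reqs = vc.level_requirements(350.0)
        assert round(reqs["supporting"], 2) == 2.08
        assert round(reqs["strong"], 1) == 18.7

    def test_independent_exp_log_evaluation_for_c_8511(self):
        expected = math.exp(math.log(8511.0) / 8.0)
        assert vc.level_requirements(8511.0)["supporting"] == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(3.10, abs=0.005)

    def test_strictly_increasing_with_level(self):
        reqs = vc.level_requirements(42.0)
        assert (reqs["supporting"] < reqs["moderate"] < reqs["strong"]
                < reqs["very_strong"])

    def test_degenerate_c_rejected(self):
        with pytest.raises(ValueError, match="c must be > 1"):
            vc.level_requirements(1.0)


class TestCombineEvidence:
    def test_eight_supporting_equal_one_very_strong(self):
        assert vc.combine_evidence(EvidenceCounts(n_su=8), 350.0) == pytest.approx(350.0)
        assert vc.combine_evidence(EvidenceCounts(n_vs=1), 350.0) == pytest.approx(350.0)

    def test_very_strong_plus_strong(self):
        combined = vc.combine_evidence(EvidenceCounts(n_st=1, n_vs=1), 350.0)
        assert combined == pytest.approx(350.0 ** 1.5)

    def test_strong_plus_two_supporting(self):
        combined = vc.combine_evidence(EvidenceCounts(n_su=2, n_st=1), 350.0)
        assert combined == pytest.approx(350.0 ** 0.75)
        assert combined == pytest.approx(80.9, abs=0.05)

    @given(st.integers(0, 4), st.integers(0, 4), st.integers(0, 3),
           st.integers(0, 2), st.integers(0, 4), st.integers(0, 4),
           st.integers(0, 3), st.integers(0, 2))
    def test_multiplicativity(self, a1, a2, a3, a4, b1, b2, b3, b4):
        c = 351.0
        a = EvidenceCounts(a1, a2, a3, a4)
        b = EvidenceCounts(b1, b2, b3, b4)
        assert vc.combine_evidence(a, c) * vc.combine_evidence(b, c) == pytest.approx(
            vc.combine_evidence(a + b, c), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            EvidenceCounts(n_su=-1)


class TestPosteriorFromLr:
    def test_printed_worked_examples(self):
        assert round(vc.posterior_from_lr(6.0, 0.21), 1) == 0.6
        assert round(vc.posterior_from_lr(15.0, 0.25), 1) == 0.8

    def test_shipped_worked_example_file(self):
        import pathlib

        import yaml

        path = pathlib.Path(__file__).resolve().parent.parent / "examples" \
            / "worked_posteriors.yaml"
        cases = yaml.safe_load(path.read_text())
        results = {case["name"]: vc.posterior_from_lr(case["lr_plus"],
                                                      case["prior"])
                   for case in cases}
        assert round(results["abundance-predictor-moderate-lr"], 1) == 0.6
        assert round(results["enzyme-activity-predictor-high-lr"], 1) == 0.8

    def test_unit_lr_returns_prior(self):
        for alpha in (0.01, 0.1, 0.5, 0.9):
            assert vc.posterior_from_lr(1.0, alpha) == pytest.approx(alpha)

    def test_strictly_increasing_in_lr(self):
        posts = [vc.posterior_from_lr(lr, 0.1) for lr in (0.5, 1.0, 2.0, 10.0, 1e6)]
        assert all(a < b for a, b in zip(posts, posts[1:]))

    @given(st.floats(1e-3, 1e6), st.sampled_from([0.01, 0.1, 0.5]))
    def test_round_trip_with_inverse(self, lr, alpha):
        post = vc.posterior_from_lr(lr, alpha)
        assert vc.lr_from_posterior(post, alpha) == pytest.approx(lr, rel=1e-10)

    def test_infinite_lr_gives_certainty(self):
        assert vc.posterior_from_lr(math.inf, 0.01) == 1.0


class TestEvidenceThresholds:
    def test_constant_curve_reaches_three_levels(self):
        model = vc.EvidenceModel(c=351.0, prior=0.1)
        lr_value = model.level_requirements["strong"] + 0.1
        curve = make_curve(np.arange(5.0), np.full(5, lr_value))
        taus = vc.evidence_thresholds(curve, model)
        assert taus["supporting"] == taus["moderate"] == taus["strong"] == 0.0
        assert taus["very_strong"] is None

    def test_unreachable_requirements_give_all_absent(self):
        model = vc.EvidenceModel(c=351.0, prior=0.1)
        curve = make_curve(np.arange(5.0), np.full(5, 1.01))
        assert all(v is None for v in vc.evidence_thresholds(curve, model).values())

    def test_interior_dip_pushes_threshold_past_it(self):
        """The for-all quantifier: a sawtooth dip invalidates earlier crossings."""
        model = vc.EvidenceModel(c=351.0, prior=0.1)
        req = model.level_requirements["supporting"]
        grid = np.arange(20.0)
        lr = np.full(20, req + 1.0)
        lr[:3] = req - 1.0
        lr[10] = req - 0.5  # interior dip below the requirement
        curve = make_curve(grid, lr)
        taus = vc.evidence_thresholds(curve, model)

        # exhaustive scan oracle over all candidate grid thresholds
        expected = None
        for i in range(20):
            if np.all(lr[i:] >= req):
                expected = grid[i]
                break
        assert expected == 11.0
        assert taus["supporting"] == expected

    def test_thresholds_nondecreasing_with_level(self, rng):
        model = vc.EvidenceModel(c=351.0, prior=0.1)
        for _ in range(20):
            lr = np.exp(rng.normal(1.0, 2.0, size=30))
            taus = vc.evidence_thresholds(make_curve(np.arange(30.0), lr), model)
            present = [taus[lv] for lv in vc.LEVELS if taus[lv] is not None]
            assert present == sorted(present)


class TestFractionReaching:
    def test_threshold_below_all_scores_gives_one(self, small_binary):
        frac = vc.fraction_reaching(small_binary, {"supporting": -10.0}, 0.1)
        assert frac["supporting"] == pytest.approx(1.0)

    def test_collapses_to_tpr_when_rates_equal(self):
        # all scores tied: TPR = FPR = 1 at any tau below them
        ls = vc.LabeledScores(["a", "b", "c", "d"], [1.0] * 4, [1, 0, 1, 0])
        for alpha in (0.05, 0.5, 0.9):
            assert vc.fraction_reaching(ls, {"supporting": 0.5}, alpha)[
                "supporting"] == pytest.approx(1.0)

    def test_direct_substitution(self):
        # TPR=0.6, FPR=0.1 at tau=1: PPP = 0.1*0.6 + 0.9*0.1 = 0.15
        scores = np.r_[np.full(6, 2.0), np.full(4, 0.0),
                       np.full(1, 2.0), np.full(9, 0.0)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        ls = vc.LabeledScores([f"v{i}" for i in range(20)], scores, labels)
        frac = vc.fraction_reaching(ls, {"supporting": 1.0}, 0.1)
        assert frac["supporting"] == pytest.approx(0.15)

    def test_absent_threshold_propagates_none(self, small_binary):
        out = vc.fraction_reaching(small_binary, {"very_strong": None}, 0.1)
        assert out["very_strong"] is None


class TestSolveC:
    def test_single_supporting_rule_closed_form(self):
        # c * 0.5 / ((c-1) * 0.5 + 1) >= 0.99  <=>  c >= 99
        rules = [(EvidenceCounts(n_su=8), "pathogenic")]
        assert vc.solve_c(0.5, rules) == 99

    def test_degenerate_targets_need_no_evidence(self):
        rules = [(EvidenceCounts(n_su=1), "pathogenic")]
        c = vc.solve_c(0.5, rules, targets={"pathogenic": 0.5,
                                            "likely_pathogenic": 0.5})
        assert c == 2

    def test_smaller_prior_needs_larger_c(self):
        rules = [
            (EvidenceCounts(n_vs=1, n_st=1), "pathogenic"),
            (EvidenceCounts(n_st=1, n_su=2), "likely_pathogenic"),
        ]
        cs = [vc.solve_c(alpha, rules) for alpha in (0.01, 0.05, 0.1, 0.25)]
        assert cs == sorted(cs, reverse=True)
        assert len(set(cs)) == len(cs)

    def test_returned_c_is_minimal_integer(self):
        rules = [(EvidenceCounts(n_su=8), "pathogenic")]
        c = vc.solve_c(0.5, rules)
        assert vc.posterior_from_lr(vc.combine_evidence(rules[0][0], c), 0.5) >= 0.99
        assert vc.posterior_from_lr(
            vc.combine_evidence(rules[0][0], c - 1), 0.5) < 0.99

    def test_empty_rules_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            vc.solve_c(0.1, [])

    def test_unreachable_cap_is_error(self):
        rules = [(EvidenceCounts(n_su=1), "pathogenic")]
        with pytest.raises(ValueError, match="cap"):
            vc.solve_c(1e-9, rules, cap=10.0)
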
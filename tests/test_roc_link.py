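"""ROC curves, Youden vs net-benefit cutoff selection, dichotomized curves."""

import numpy as np
import pytest

from decurve import (
    DomainError,
    InvalidInputError,
    PredictionSet,
    ThresholdGrid,
    classify,
    decision_curve,
    dichotomized_curve,
    net_benefit,
    netbenefit_cutoff,
    reference_curve,
    roc_points,
    sens_spec_net_benefit,
    youden_cutoff,
)
from conftest import enumerate_classifications, random_prediction_set

TOL = 1e-12


def make_preds(probs, outcomes):
    return PredictionSet(outcomes=np.asarray(outcomes), probabilities=np.asarray(probs))


def ninety_ninety_preds():
    """0/1 predictions realising exactly 90% sensitivity and specificity."""
    outcomes = np.array([1] * 450 + [0] * 50 + [1] * 50 + [0] * 450)
    probs = np.array([1.0] * 500 + [0.0] * 500)
    return PredictionSet(outcomes=outcomes, probabilities=probs)


class TestRocPoints:
    def test_hand_enumerated_interior_points(self):
        roc = roc_points(make_preds([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]))
        interior = [tuple(p) for p in roc.points[1:-1]]
        assert interior == [(0.0, 0.5), (0.5, 0.5), (0.5, 1.0)]

    def test_endpoints_and_monotonicity(self, rng):
        for _ in range(20):
            preds = random_prediction_set(rng, int(rng.integers(2, 200)))
            roc = roc_points(preds)
            assert tuple(roc.points[0]) == (0.0, 0.0)
            assert tuple(roc.points[-1]) == (1.0, 1.0)
            assert (np.diff(roc.points[:, 0]) >= 0).all()
            assert (np.diff(roc.points[:, 1]) >= 0).all()
            assert (np.diff(roc.cutoffs) < 0).all()

    def test_perfect_predictions_pass_through_top_left(self):
        y = np.array([1, 1, 0, 0])
        roc = roc_points(PredictionSet(outcomes=y, probabilities=y.astype(float)))
        assert any(tuple(p) == (0.0, 1.0) for p in roc.points)

    def test_constant_predictions_have_only_trivial_points(self):
        roc = roc_points(make_preds([0.4, 0.4, 0.4], [1, 0, 1]))
        assert [tuple(p) for p in roc.points] == [(0.0, 0.0), (1.0, 1.0)]

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_points(make_preds([0.2, 0.8], [1, 1]))

    def test_point_set_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 500))
            preds = random_prediction_set(rng, n)
            roc = roc_points(preds)
            expected = {
                (round(1 - spec, 12), round(sens, 12))
                for sens, spec in enumerate_classifications(
                    preds.outcomes.tolist(), preds.probabilities.tolist()
                )
            }
            got = {(round(x, 12), round(y, 12)) for x, y in roc.points}
            assert got == expected


class TestYoudenCutoff:
    def test_ninety_ninety_test_has_youden_point_eight(self):
        op = youden_cutoff(roc_points(ninety_ninety_preds()))
        assert op.criterion_value == pytest.approx(0.8, abs=TOL)
        assert op.sensitivity == pytest.approx(0.9, abs=TOL)
        assert op.specificity == pytest.approx(0.9, abs=TOL)

    def test_perfect_predictions_reach_youden_one(self):
        y = np.array([1, 0, 1, 0])
        op = youden_cutoff(roc_points(PredictionSet(outcomes=y, probabilities=y.astype(float))))
        assert op.criterion_value == 1.0
        assert (op.sensitivity, op.specificity) == (1.0, 1.0)

    def test_constant_predictions_have_zero_youden(self):
        op = youden_cutoff(roc_points(make_preds([0.4, 0.4, 0.4], [1, 0, 1])))
        assert op.criterion_value == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            preds = random_prediction_set(rng, int(rng.integers(2, 500)))
            op = youden_cutoff(roc_points(preds))
            best = max(
                sens + spec - 1.0
                for sens, spec in enumerate_classifications(
                    preds.outcomes.tolist(), preds.probabilities.tolist()
                )
            )
            assert op.criterion_value == pytest.approx(best, abs=TOL)


class TestNetBenefitCutoff:
    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            preds = random_prediction_set(rng, int(rng.integers(2, 500)))
            p_t = float(rng.uniform(0.05, 0.95))
            pi = preds.prevalence
            w = p_t / (1.0 - p_t)
            op = netbenefit_cutoff(preds, p_t)
            candidates = [
                (sens * pi - (1 - spec) * (1 - pi) * w, spec)
                for sens, spec in enumerate_classifications(
                    preds.outcomes.tolist(), preds.probabilities.tolist()
                )
            ]
            best = max(u for u, _ in candidates)
            assert op.criterion_value == pytest.approx(best, abs=TOL)
            best_spec = max(s for u, s in candidates if u >= best - TOL)
            assert op.specificity == pytest.approx(best_spec, abs=TOL)

    def test_threshold_at_prevalence_recovers_youden_cutoff(self, rng):
        # u_treated at p_t = pi equals pi * (Youden index) at every cutoff,
        # so the two selection rules coincide exactly
        for _ in range(50):
            preds = random_prediction_set(rng, int(rng.integers(4, 200)))
            pi = preds.prevalence
            if not (0.0 < pi < 1.0):
                continue
            op_nb = netbenefit_cutoff(preds, pi)
            op_youden = youden_cutoff(roc_points(preds))
            assert op_nb.cutoff == op_youden.cutoff
            assert op_nb.criterion_value == pytest.approx(
                pi * op_youden.criterion_value, abs=TOL
            )

    def test_target_slope_diagnostic(self):
        # prevalence 0.3, p_t = 0.2: slope (0.7/0.3)(0.2/0.8) = 7/12
        outcomes = np.array([1] * 3 + [0] * 7)
        preds = PredictionSet(outcomes=outcomes, probabilities=np.linspace(0.05, 0.95, 10))
        op = netbenefit_cutoff(preds, 0.2)
        assert op.target_slope == pytest.approx(7 / 12, abs=TOL)

    def test_perfect_predictions_attain_prevalence(self):
        y = np.array([1, 1, 0, 0, 0])
        preds = PredictionSet(outcomes=y, probabilities=y.astype(float))
        for p_t in (0.2, 0.5, 0.8):
            op = netbenefit_cutoff(preds, p_t)
            assert op.criterion_value == pytest.approx(0.4, abs=TOL)
            assert (op.sensitivity, op.specificity) == (1.0, 1.0)

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(DomainError):
            netbenefit_cutoff(make_preds([0.3, 0.7], [0, 1]), 1.0)


class TestSensSpecNetBenefit:
    def test_ninety_ninety_treated(self):
        assert sens_spec_net_benefit(0.9, 0.9, 0.5, 0.5, "treated") == pytest.approx(
            0.40, abs=TOL
        )

    def test_perfect_test_overall_is_one(self):
        for pi in (0.1, 0.5, 0.9):
            assert sens_spec_net_benefit(1.0, 1.0, pi, 0.3, "overall") == pytest.approx(
                1.0, abs=TOL
            )

    def test_identity_with_proportion_form(self, rng):
        # substituting the induced proportions must give the same number
        for _ in range(200):
            preds = random_prediction_set(rng, int(rng.integers(4, 100)))
            p_t = float(rng.uniform(0.05, 0.95))
            props = classify(preds, p_t)
            pi = props.prevalence
            if not (0.0 < pi < 1.0):
                continue
            sens = props.a / (props.a + props.c)
            spec = props.d / (props.b + props.d)
            for kind in ("treated", "untreated", "overall"):
                assert sens_spec_net_benefit(sens, spec, pi, p_t, kind) == pytest.approx(
                    net_benefit(props, p_t, kind), abs=TOL
                )

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(DomainError):
            sens_spec_net_benefit(0.9, 0.9, 0.5, 0.0, "treated")


class TestDichotomizedCurve:
    def test_agrees_with_continuous_curve_at_the_cutoff(self, rng):
        preds = random_prediction_set(rng, 300)
        grid = ThresholdGrid.default()
        cutoff = 0.4  # a grid point
        dichotomized = dichotomized_curve(preds, cutoff, grid, "treated")
        continuous = decision_curve(preds, grid, "treated")
        k = int(np.flatnonzero(np.isclose(grid.values, cutoff))[0])
        assert dichotomized.net_benefits[k] == continuous.net_benefits[k]

    def test_hand_computed_value_off_the_cutoff(self):
        # 90%/90% test data dichotomized at the separating cutoff, p_t = 0.25
        curve = dichotomized_curve(ninety_ninety_preds(), 0.5, [0.25], "treated")
        assert curve.net_benefits[0] == pytest.approx(0.45 - 0.05 / 3, abs=TOL)

    def test_classification_is_constant_across_grid(self, rng):
        preds = random_prediction_set(rng, 100)
        props = classify(preds, 0.3)
        curve = dichotomized_curve(preds, 0.3, ThresholdGrid.default(), "treated")
        expected = [net_benefit(props, t, "treated") for t in curve.thresholds]
        np.testing.assert_allclose(curve.net_benefits, expected, atol=TOL)

    def test_arc_drops_below_both_references_far_from_cutoff(self):
        """On well-separated data the dichotomized model is beaten by
        treat-none at high thresholds and treat-all at low ones."""
        preds = ninety_ninety_preds()
        grid = ThresholdGrid.default()
        arc = dichotomized_curve(preds, 0.5, grid, "treated").net_benefits
        none = reference_curve(0.5, grid, "treat_none", "treated").net_benefits
        allc = reference_curve(0.5, grid, "treat_all", "treated").net_benefits
        hi = grid.values >= 0.95
        lo = grid.values <= 0.05
        assert (arc[hi] < none[hi]).all()
        assert (arc[lo] < allc[lo]).all()


def test_youden_identity_exact_at_prevalence_threshold(rng):
    """u_treated at p_t = pi equals pi * (sens + spec - 1) at every cutoff."""
    for _ in range(100):
        preds = random_prediction_set(rng, int(rng.integers(4, 100)))
        pi = preds.prevalence
        for sens, spec in enumerate_classifications(
            preds.outcomes.tolist(), preds.probabilities.tolist()
        ):
            u = sens_spec_net_benefit(sens, spec, pi, pi, "treated")
            assert u == pytest.approx(pi * (sens + spec - 1), abs=TOL)
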
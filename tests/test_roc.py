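"""ROC/AUC computation, bootstrap CI and optimism correction."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from exposurekit import (
    auc_mann_whitney,
    bootstrap_auc_ci,
    endpoint_labels,
    evaluate_score,
    fixture,
    optimism_corrected_auc,
    roc_curve,
)
from exposurekit.roc import delong_auc_ci


def _exhaustive_auc(scores, labels):
    """Brute-force pair-concordance oracle: O(n1 * n0)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _table7_scores_labels():
    fx = fixture("table7_tnm_score")
    levels = {"low": 0, "medium": 1, "high": 2}
    scores = [levels[c] for _, c in fx.expansion]
    labels = [1 if stage == "IV" else 0 for stage, _ in fx.expansion]
    return np.array(scores), np.array(labels)


class TestAucMannWhitney:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_three_class_surrogate_on_published_stage_table(self):
        scores, labels = _table7_scores_labels()
        assert labels.sum() == 89 and (1 - labels).sum() == 42
        auc = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(2691 / 3738)
        assert auc == pytest.approx(_exhaustive_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_and_reference_library(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=60).astype(float)
        labels = rng.integers(0, 2, size=60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(_exhaustive_auc(scores, labels))
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_complement_symmetry(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert auc_mann_whitney(scores, labels) + auc_mann_whitney(
            scores, 1 - labels
        ) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])


class TestRocCurve:
    def test_three_level_score_gives_four_points(self):
        scores, labels = _table7_scores_labels()
        curve = roc_curve(scores, labels)
        assert len(curve) == 4                       # (0,0) + one per threshold
        assert curve[0] == (0.0, 0.0) and curve[-1] == (1.0, 1.0)

    def test_curve_is_monotone(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        pts = np.array(roc_curve(scores, labels))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_area_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, size=40).astype(float)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pts = np.array(roc_curve(scores, labels))
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc_mann_whitney(scores, labels))

    def test_reversing_sign_flips_auc(self):
        scores, labels = _table7_scores_labels()
        assert auc_mann_whitney(-scores, labels) == pytest.approx(
            1 - auc_mann_whitney(scores, labels)
        )


class TestBootstrapCI:
    def test_perfect_separation_interval_at_one(self):
        scores = np.r_[np.zeros(100), np.ones(100)]
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        low, high = bootstrap_auc_ci(scores, labels, B=200, seed=1)
        assert low == high == 1.0

    def test_fixed_seed_reproducible(self):
        scores, labels = _table7_scores_labels()
        a = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        assert a == bootstrap_auc_ci(scores, labels, B=300, seed=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_interval_contains_apparent_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60) + rng.integers(0, 2, size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        low, high = bootstrap_auc_ci(scores, labels, B=300, seed=seed)
        assert low <= auc_mann_whitney(scores, labels) <= high

    def test_delong_alternative_brackets_auc(self):
        scores, labels = _table7_scores_labels()
        low, high = delong_auc_ci(scores, labels)
        assert low < auc_mann_whitney(scores, labels) < high


class TestOptimismCorrection:
    def test_fixed_score_correction_is_small(self):
        scores, labels = _table7_scores_labels()
        corrected, optimism = optimism_corrected_auc(scores, labels, B=1000, seed=2)
        apparent = auc_mann_whitney(scores, labels)
        assert abs(corrected - apparent) < 0.01
        assert abs(optimism) < 0.01

    def test_perfect_separation_stays_perfect(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        corrected, _ = optimism_corrected_auc(scores, labels, B=200, seed=3)
        assert corrected == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        scores, labels = _table7_scores_labels()
        assert optimism_corrected_auc(scores, labels, B=200, seed=9) == \
            optimism_corrected_auc(scores, labels, B=200, seed=9)


class TestEndpoints:
    def test_stage_endpoints_label_positive_sets(self, synthetic_cohort):
        y4 = endpoint_labels(synthetic_cohort, "stageIV_vs_rest")
        y34 = endpoint_labels(synthetic_cohort, "stageIII_IV_vs_I_II")
        stages = [r.tnm_stage for r in synthetic_cohort]
        assert y4.sum() == stages.count("IV")
        assert y34.sum() == stages.count("III") + stages.count("IV")
        assert (y34 >= y4).all()

    def test_unknown_endpoint_rejected(self, synthetic_cohort):
        with pytest.raises(ValueError, match="unknown endpoint"):
            endpoint_labels(synthetic_cohort, "stageX")

    def test_evaluate_score_bundles_everything(self):
        scores, labels = _table7_scores_labels()
        result = evaluate_score(scores, labels, endpoint="stageIV_vs_rest",
                                B=200, seed=4)
        assert result.auc == pytest.approx(2691 / 3738)
        assert result.ci_low <= result.auc <= result.ci_high
        assert result.n_positive == 89 and result.n_negative == 42
        assert len(result.curve) == 4
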
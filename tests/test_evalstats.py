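"""Evaluation statistics: splits, confusion metrics, AUC, bootstrap, DeLong."""

import numpy as np
import pytest
from scipy import stats as sps

from invadenet.evalstats import (
    CohortSplit,
    bootstrap_ci,
    cohort_summary,
    confusion_metrics,
    delong_test,
    evaluate_scores,
    roc_auc,
    split_cohort,
)


@pytest.fixture(scope="module")
def cohort_184():
    rng = np.random.default_rng(0)
    ids = np.array([f"P{i:03d}" for i in range(184)])
    labels = np.zeros(184, int)
    labels[:48] = 1
    rng.shuffle(labels)
    return ids, labels


class TestSplitCohort:
    def test_explicit_counts_honoured(self, cohort_184):
        ids, labels = cohort_184
        sp = split_cohort(ids, labels, counts=(115, 20, 49), seed=1)
        assert (len(sp.train_ids), len(sp.val_ids), len(sp.test_ids)) == (115, 20, 49)

    def test_same_seed_same_split(self, cohort_184):
        ids, labels = cohort_184
        a = split_cohort(ids, labels, counts=(115, 20, 49), seed=5)
        b = split_cohort(ids, labels, counts=(115, 20, 49), seed=5)
        assert a == b

    def test_stratification_within_one_sample(self, cohort_184):
        ids, labels = cohort_184
        lab = dict(zip(ids, labels))
        sp = split_cohort(ids, labels, counts=(115, 20, 49), seed=2)
        global_frac = labels.mean()
        for part in (sp.train_ids, sp.val_ids, sp.test_ids):
            n_inv = sum(lab[i] for i in part)
            assert abs(n_inv - global_frac * len(part)) <= 1.0

    def test_ratio_based_split_partitions_cohort(self, cohort_184):
        ids, labels = cohort_184
        sp = split_cohort(ids, labels, seed=3)  # 6:1:3 default
        all_ids = set(sp.train_ids) | set(sp.val_ids) | set(sp.test_ids)
        assert all_ids == set(ids)
        for part, frac in ((sp.train_ids, 0.6), (sp.val_ids, 0.1), (sp.test_ids, 0.3)):
            assert abs(len(part) - frac * 184) < 1.0

    def test_bad_counts_rejected(self, cohort_184):
        ids, labels = cohort_184
        with pytest.raises(ValueError):
            split_cohort(ids, labels, counts=(184, 20, 49), seed=0)

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError):
            CohortSplit(("a", "b"), ("b",), ("c",))


class TestConfusionMetrics:
    def test_perfect_scores(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        s = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        r = confusion_metrics(s, y)
        assert (r.sensitivity, r.specificity, r.accuracy, r.auc) == (1, 1, 1, 1)

    def test_hand_confusion_table(self):
        # TP=9, FN=1, TN=7, FP=3
        s = np.r_[np.repeat(0.9, 9), 0.1, np.repeat(0.2, 7), np.repeat(0.8, 3)]
        y = np.r_[np.ones(10), np.zeros(10)]
        r = confusion_metrics(s, y)
        assert r.sensitivity == pytest.approx(0.9)
        assert r.specificity == pytest.approx(0.7)
        assert r.accuracy == pytest.approx(0.8)
        assert r.per_class_recall["noninvasive"] == pytest.approx(0.7)

    def test_accuracy_identity(self, rng):
        """acc == (sens*n_pos + spec*n_neg) / n exactly."""
        y = rng.integers(0, 2, 200).astype(float)
        y[:2] = [0, 1]
        s = rng.random(200)
        r = confusion_metrics(s, y)
        assert r.accuracy == pytest.approx(
            (r.sensitivity * r.n_pos + r.specificity * r.n_neg)
            / (r.n_pos + r.n_neg),
            abs=1e-12,
        )

    def test_inverted_scores_flip_confusion_counts(self, rng):
        """1-score swaps the roles of the two classes in the brute-force
        confusion table (strictly away from the 0.5 threshold)."""
        y = rng.integers(0, 2, 100).astype(float)
        y[:2] = [0, 1]
        s = np.where(rng.random(100) < 0.5, 0.2, 0.8)
        r = confusion_metrics(s, y)
        r_inv = confusion_metrics(1.0 - s, y)
        assert r_inv.sensitivity == pytest.approx(1.0 - r.sensitivity)
        assert r_inv.specificity == pytest.approx(1.0 - r.specificity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0.5, 0.6], [1, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_is_half(self):
        auc, _, _ = roc_auc([0.5] * 10, [1, 1, 0, 0, 1, 0, 0, 1, 0, 0])
        assert auc == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 10_000)
        auc, _, _ = roc_auc(rng.random(10_000), y)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_trapezoidal_integration(self, rng):
        """Rank-based AUC equals explicit trapezoidal ROC integration."""
        for _ in range(5):
            y = rng.integers(0, 2, 300)
            y[:2] = [0, 1]
            s = np.round(rng.random(300), 2)  # ties included
            auc, fpr, tpr = roc_auc(s, y)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)


class TestBootstrap:
    def test_point_within_interval(self, rng):
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        s = rng.random(120) + 0.3 * y
        lo, hi = bootstrap_ci(s, y, "auc", B=300, seed=1)
        auc, _, _ = roc_auc(s, y)
        assert lo <= auc <= hi

    def test_fixed_seed_reproducible(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s = rng.random(80)
        assert bootstrap_ci(s, y, "auc", B=200, seed=9) == bootstrap_ci(
            s, y, "auc", B=200, seed=9
        )

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 500):
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = rng.random(n) + 0.8 * y
            lo, hi = bootstrap_ci(s, y, "auc", B=400, seed=4)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.1, 0.9], [0, 1], B=10)


class TestDelong:
    def test_identical_scores_give_null_result(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.random(60)
        r = delong_test(s, s, y)
        assert r.z == 0.0 and r.p_raw == 1.0

    def test_bonferroni_caps_at_one(self, rng):
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        base = rng.standard_normal(60) + 0.3 * y
        a = base + rng.standard_normal(60)
        b = base + rng.standard_normal(60)
        r = delong_test(a, b, y, m_comparisons=4)
        assert r.p_adjusted == min(1.0, 4 * r.p_raw)
        assert r.p_adjusted <= 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1], [1, 0])

    def test_type_one_error_calibrated(self):
        """Under the null (two equally informative correlated score sets),
        the rejection rate at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            y = np.r_[np.ones(20, int), np.zeros(40, int)]
            base = rng.standard_normal(60) + 0.5 * y
            a = base + rng.standard_normal(60)
            b = base + rng.standard_normal(60)
            rejections += delong_test(a, b, y).p_raw < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_agrees_with_permutation_oracle(self):
        """DeLong p within Monte-Carlo error of a paired sign-flip
        permutation test on the AUC difference."""
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        base = rng.standard_normal(60) + 0.6 * y
        a = base + 0.8 * rng.standard_normal(60)
        b = base + 0.8 * rng.standard_normal(60)
        p_delong = delong_test(a, b, y).p_raw
        p_perm = _permutation_p(a, b, y, n_perm=4000, seed=1)
        assert abs(p_delong - p_perm) < 0.06


def _fast_auc_rows(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Mann-Whitney AUC per row of a (B, n) score matrix."""
    ranks = sps.rankdata(scores, axis=1)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (ranks[:, y == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _permutation_p(a, b, y, n_perm=10_000, seed=0):
    rng = np.random.default_rng(seed)
    obs = roc_auc(a, y)[0] - roc_auc(b, y)[0]
    flips = rng.random((n_perm, len(y))) < 0.5
    pa = np.where(flips, b, a)
    pb = np.where(flips, a, b)
    diffs = _fast_auc_rows(pa, y) - _fast_auc_rows(pb, y)
    return float((np.abs(diffs) >= abs(obs) - 1e-12).mean())


class TestCohortSummary:
    def test_published_style_percentages(self):
        labels = np.r_[np.zeros(136, int), np.ones(48, int)]
        df = cohort_summary(labels)
        row = df[(df["stratum"] == "all") & (df["class"] == "noninvasive")].iloc[0]
        assert row["count"] == 136 and row["percent"] == 73.9
        row = df[(df["stratum"] == "all") & (df["class"] == "invasive")].iloc[0]
        assert row["count"] == 48 and row["percent"] == 26.1

    def test_zero_count_stratum(self):
        df = cohort_summary(np.zeros(10, int))
        inv = df[df["class"] == "invasive"].iloc[0]
        assert inv["count"] == 0 and inv["percent"] == 0.0

    def test_strata_breakdown(self):
        labels = np.array([0, 0, 1, 1])
        df = cohort_summary(labels, strata={"sex": np.array(["f", "m", "f", "m"])})
        f_inv = df[(df["stratum"] == "sex") & (df["group"] == "f")
                   & (df["class"] == "invasive")].iloc[0]
        assert f_inv["count"] == 1 and f_inv["percent"] == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(np.array([]))


def test_evaluate_scores_attaches_cis(rng):
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.random(100) + 0.5 * y
    report = evaluate_scores(s, y, B=200, seed=0)
    for metric in ("sensitivity", "specificity", "accuracy", "auc"):
        lo, hi = report.ci[metric]
        assert lo <= getattr(report, metric) <= hi
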
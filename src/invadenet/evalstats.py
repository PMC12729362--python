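"""Cohort evaluation statistics.

Conventions: the positive class is muscle invasion (label 1); non-invasive
cases are negative.  Because clinical reports sometimes quote "sensitivity
for NMIBC" (i.e. recall of the negative class), every report also carries
per-class recall so both readings are available.

AUCs are rank-based (Mann-Whitney with tie correction) and cross-checked
against trapezoidal ROC integration; paired AUCs are compared with DeLong's
covariance-based test, Bonferroni-adjusted when several models are compared
against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as sk_roc_curve

__all__ = [
    "EvalReport",
    "DelongResult",
    "CohortSplit",
    "split_cohort",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_ci",
    "delong_test",
    "cohort_summary",
    "evaluate_scores",
]


@dataclass(frozen=True)
class EvalReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_pos: int
    n_neg: int
    per_class_recall: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)  # metric -> (low, high)
    positive_class: str = "invasive (MIBC)"
    negative_class: str = "non-invasive (NMIBC)"

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy", "auc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, (lo, hi) in self.ci.items():
            point = getattr(self, name)
            if not lo <= point <= hi:
                raise ValueError(f"{name} CI ({lo}, {hi}) excludes point {point}")

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "per_class_recall": self.per_class_recall,
        }
        d.update({f"{k}_ci": list(v) for k, v in self.ci.items()})
        return d


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split ids are not disjoint")


def split_cohort(
    ids,
    labels,
    counts: tuple[int, int, int] | None = None,
    ratio: tuple[float, float, float] = (6.0, 1.0, 3.0),
    seed: int = 0,
) -> CohortSplit:
    """Seeded stratified train/validation/test assignment.

    Explicit ``counts`` (e.g. (115, 20, 49)) override the ratio; per-split
    class fractions match the cohort fraction to within one sample.
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    n = len(ids)
    if len(labels) != n:
        raise ValueError("ids and labels differ in length")
    if counts is None:
        total = float(sum(ratio))
        raw = [r / total * n for r in ratio]
        counts = [int(np.floor(c)) for c in raw]
        rema = np.argsort([-(c - f) for c, f in zip(raw, counts)])
        for k in range(n - sum(counts)):
            counts[rema[k % 3]] += 1
        counts = tuple(counts)
    if sum(counts) != n:
        raise ValueError(f"split counts {counts} do not sum to cohort size {n}")
    rng = np.random.default_rng(seed)
    fractions = np.array(counts, dtype=float) / n
    buckets: list[list] = [[], [], []]
    remaining = list(counts)
    classes = np.unique(labels)
    for c in classes:
        members = ids[labels == c]
        rng.shuffle(members)
        raw = fractions * len(members)
        alloc = np.floor(raw).astype(int)
        order = np.argsort(-(raw - alloc))
        leftover = len(members) - alloc.sum()
        for k in range(leftover):
            alloc[order[k % 3]] += 1
        # keep global counts feasible
        for s in range(3):
            alloc[s] = min(alloc[s], remaining[s])
        while alloc.sum() < len(members):
            for s in np.argsort(-np.array(remaining)):
                if remaining[s] > alloc[s]:
                    alloc[s] += 1
                    break
        pos = 0
        for s in range(3):
            buckets[s].extend(members[pos : pos + alloc[s]])
            remaining[s] -= alloc[s]
            pos += alloc[s]
    return CohortSplit(
        train_ids=tuple(buckets[0]), val_ids=tuple(buckets[1]), test_ids=tuple(buckets[2])
    )


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    if not (pos | neg).all():
        raise ValueError("labels must be binary 0/1")
    return pos, neg


def confusion_metrics(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Threshold the scores and report sensitivity = TP/(TP+FN) for the
    invasive class, specificity, accuracy, and per-class recall."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & neg).sum())
    fp = int((pred & neg).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(scores)
    auc, _, _ = roc_auc(scores, labels)
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
        per_class_recall={"invasive": sens, "noninvasive": spec},
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """Rank-based (Mann-Whitney) AUC with tie correction, plus the ROC
    curve for plotting/integration."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = sps.rankdata(scores)  # average ranks handle ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = sk_roc_curve(np.asarray(labels), scores)
    return float(auc), fpr, tpr


_METRICS = {
    "auc": lambda s, y: roc_auc(s, y)[0],
    "sensitivity": lambda s, y: confusion_metrics(s, y).sensitivity,
    "specificity": lambda s, y: confusion_metrics(s, y).specificity,
    "accuracy": lambda s, y: confusion_metrics(s, y).accuracy,
}


def bootstrap_ci(
    scores,
    labels,
    metric: str = "auc",
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified bootstrap percentile interval; resamples that leave a
    metric undefined are skipped (their count is tracked on the function
    as ``bootstrap_ci.last_skipped``)."""
    if B < 100:
        raise ValueError("B must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    _check_two_class(labels)
    fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        try:
            values.append(fn(scores[take], labels[take]))
        except ValueError:
            skipped += 1
    bootstrap_ci.last_skipped = skipped
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


bootstrap_ci.last_skipped = 0


def _delong_components(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Structural components: V10 over positives, V01 over negatives."""
    xs = scores[pos][:, None]
    ys = scores[neg][None, :]
    psi = (xs > ys).astype(float) + 0.5 * (xs == ys)
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def delong_test(scores_a, scores_b, labels, m_comparisons: int = 1) -> DelongResult:
    """DeLong's test for two correlated (paired) AUCs with Bonferroni
    adjustment p_adj = min(1, m * p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores must have identical lengths")
    pos, neg = _check_two_class(labels)
    v10_a, v01_a, auc_a = _delong_components(scores_a, pos, neg)
    v10_b, v01_b, auc_b = _delong_components(scores_b, pos, neg)
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2 over positives
    s01 = np.cov(np.vstack([v01_a, v01_b]))  # 2x2 over negatives
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if delta == 0:
        z, p = 0.0, 1.0
    return DelongResult(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        z=float(z),
        p_raw=p,
        p_adjusted=min(1.0, m_comparisons * p),
        m_comparisons=m_comparisons,
    )


def _pct(k: int, n: int) -> float:
    """Percentage rounded half-up to one decimal (clinical-table style)."""
    if n == 0:
        return 0.0
    return float(Decimal(100.0 * k / n).quantize(Decimal("0.1"), ROUND_HALF_UP))


def cohort_summary(labels, strata: dict | None = None) -> pd.DataFrame:
    """Counts and percentages (1 decimal, half-up) per class, overall and
    within optional strata (name -> per-sample group array)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty cohort")
    rows = []
    def add(stratum, group, mask):
        n = int(mask.sum())
        for cls, name in ((0, "noninvasive"), (1, "invasive")):
            k = int(((labels == cls) & mask).sum())
            rows.append(
                {"stratum": stratum, "group": group, "class": name,
                 "count": k, "of": n, "percent": _pct(k, n)}
            )
    add("all", "all", np.ones_like(labels, dtype=bool))
    for name, groups in (strata or {}).items():
        groups = np.asarray(groups)
        for g in np.unique(groups):
            add(name, str(g), groups == g)
    return pd.DataFrame(rows)


def evaluate_scores(
    scores, labels, B: int = 2000, seed: int = 0, threshold: float = 0.5
) -> EvalReport:
    """Confusion metrics + AUC with stratified bootstrap CIs for each."""
    base = confusion_metrics(scores, labels, threshold)
    ci = {
        m: bootstrap_ci(scores, labels, m, B=B, seed=seed)
        for m in ("sensitivity", "specificity", "accuracy", "auc")
    }
    # clip CI bounds to include the point estimate (percentile intervals can
    # exclude it in tiny cohorts)
    ci = {m: (min(lo, getattr(base, m)), max(hi, getattr(base, m))) for m, (lo, hi) in ci.items()}
    return EvalReport(
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        accuracy=base.accuracy,
        auc=base.auc,
        n_pos=base.n_pos,
        n_neg=base.n_neg,
        per_class_recall=base.per_class_recall,
        ci=ci,
    )
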
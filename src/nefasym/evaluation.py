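"""Statistics for comparing an asymmetry scorer against expert labels.

Two study designs are supported.  In *rank mode* the scorer's values are
compared with ordinal clinical assessments via Spearman rank correlation
(exact permutation p-value at small n).  In *binary mode* expert classes are
binarized (fully-asymmetric class positive), and the scorer is summarized by
sensitivity/specificity at a threshold, threshold-free ROC area via the
rank-sum identity, a two-sided Fisher exact test on the confusion table, a
Wilcoxon rank-sum test between the two classes, and Cohen's d.

The module is scorer-agnostic: it consumes (scores, labels) pairs, so any
external asymmetry index can be plugged in next to the NEF-based one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LabeledScores",
    "ClassificationReport",
    "SpearmanResult",
    "RankSumResult",
    "spearman",
    "classify",
    "wilcoxon_rank_sum",
    "cohens_d",
    "evaluate_labeled",
]

ALPHA = 0.05  # significance level for all reject flags
_EXACT_SPEARMAN_MAX_N = 10
_EXACT_RANKSUM_MAX_COMB = 100_000


@dataclass(frozen=True)
class LabeledScores:
    """Parallel scorer outputs and expert labels (ordinal ranks or 0/1)."""

    scores: tuple[float, ...]
    labels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")
        if len(self.scores) < 2:
            raise ValueError("need at least two labeled scores")


@dataclass(frozen=True)
class ClassificationReport:
    """Threshold classification summary (percentages for sens/spec)."""

    sensitivity: float
    specificity: float
    auc: float
    threshold: float
    p_fisher: float
    tp: int
    fn: int
    fp: int
    tn: int

    def as_dict(self) -> dict:
        return asdict(self)


class SpearmanResult(NamedTuple):
    rho: float
    p: float


class RankSumResult(NamedTuple):
    p: float
    reject: bool


def _permutation_matrix(n: int) -> np.ndarray:
    """All permutations of range(n) as an (n!, n) int8 array."""
    perms = np.zeros((1, 1), dtype=np.int8)
    for m in range(2, n + 1):
        blocks = []
        for pos in range(m):
            block = np.empty((perms.shape[0], m), dtype=np.int8)
            block[:, :pos] = perms[:, :pos]
            block[:, pos] = m - 1
            block[:, pos + 1 :] = perms[:, pos:]
            blocks.append(block)
        perms = np.concatenate(blocks)
    return perms


def spearman(scores: Sequence[float], reference: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling.

    The two-sided p-value is exact (full enumeration of all n! pairings) for
    n <= 10 and uses the t-approximation with n-2 degrees of freedom above.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or a constant input (zero rank variance).
    """
    x = np.asarray(scores, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and reference must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    norm = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if norm == 0.0:
        raise ValueError("correlation undefined for constant input")
    rho = float(xc @ yc) / norm

    if n <= _EXACT_SPEARMAN_MAX_N:
        perms = _permutation_matrix(n)
        total = perms.shape[0]
        count = 0
        target = abs(rho) - 1e-12
        chunk = 200_000
        for start in range(0, total, chunk):
            block = perms[start : start + chunk]
            rho_perm = (yc[block] @ xc) / norm
            count += int(np.count_nonzero(np.abs(rho_perm) >= target))
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, p)


def _confusion(scores: np.ndarray, y: np.ndarray, threshold: float):
    pred = scores > threshold
    tp = int(np.count_nonzero(pred & (y == 1)))
    fn = int(np.count_nonzero(~pred & (y == 1)))
    fp = int(np.count_nonzero(pred & (y == 0)))
    tn = int(np.count_nonzero(~pred & (y == 0)))
    return tp, fn, fp, tn


def classify(
    data: LabeledScores | tuple[Sequence[float], Sequence[float]],
    threshold: float | None = None,
) -> ClassificationReport:
    """Binary classification metrics for an asymmetry scorer.

    ``score > threshold`` predicts the positive (asymmetric) class.  When no
    threshold is given, the Youden-optimal one (max sensitivity +
    specificity - 1, lowest value on ties) is chosen from the observed
    scores.  The ROC area is threshold-free, via the Mann-Whitney rank-sum
    identity (ties count one half).  ``p_fisher`` is the two-sided Fisher
    exact test of association in the resulting confusion table.
    """
    if isinstance(data, LabeledScores):
        scores, labels = data.scores, data.labels
    else:
        scores, labels = data
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(np.int64)
    n_pos = int(np.count_nonzero(y == 1))
    n_neg = int(np.count_nonzero(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(s)
    auc = (float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    if threshold is None:
        best_j = -np.inf
        threshold = float(s.min())
        for t in np.unique(s):
            tp, fn, fp, tn = _confusion(s, y, float(t))
            j = tp / (tp + fn) + tn / (tn + fp) - 1.0
            if j > best_j:
                best_j = j
                threshold = float(t)

    tp, fn, fp, tn = _confusion(s, y, threshold)
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    p_fisher = float(stats.fisher_exact([[tp, fn], [fp, tn]])[1])
    return ClassificationReport(
        sensitivity, specificity, auc, threshold, p_fisher, tp, fn, fp, tn
    )


def _rank_sum_statistic(x, y, axis):
    pooled = np.concatenate((x, y), axis=axis)
    ranks = stats.rankdata(pooled, axis=axis)
    take = x.shape[axis]
    return np.take(ranks, np.arange(take), axis=axis).sum(axis=axis)


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = ALPHA
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for equal medians.

    Small samples (both groups below 10, assignment count enumerable) get
    the exact permutation distribution of the rank sum; otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_comb = math.comb(a.size + b.size, a.size)
    if max(a.size, b.size) < 10 and n_comb <= _EXACT_RANKSUM_MAX_COMB:
        res = stats.permutation_test(
            (a, b),
            _rank_sum_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_comb + 1,
            vectorized=True,
        )
        p = float(res.pvalue)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    p = min(p, 1.0)
    return RankSumResult(p, p < alpha)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d: mean difference over the df-pooled sample deviation."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    pooled = math.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0.0:
        raise ValueError("zero pooled variance; effect size undefined")
    return (float(a.mean()) - float(b.mean())) / pooled


def evaluate_labeled(
    scores: Sequence[float],
    labels: Sequence[float],
    threshold: float | None = None,
) -> dict:
    """Full evaluation report, mode auto-detected from the labels.

    Labels within {0, 1} run binary mode directly; labels within {0, 1, 2}
    are binarized as classes 0-1 negative vs class 2 positive (the expert
    asymmetry-class convention); anything else is treated as ordinal ranks
    and evaluated with Spearman correlation only.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    values = set(np.unique(y))
    report: dict = {"n": int(s.size)}
    if values <= {0.0, 1.0}:
        binary = y.astype(int)
    elif values <= {0.0, 1.0, 2.0}:
        binary = (y == 2.0).astype(int)
    else:
        rho, p = spearman(s, y)
        report.update({"mode": "rank", "rho": rho, "p_spearman": p})
        return report

    cls = classify((s, binary), threshold=threshold)
    neg = s[binary == 0]
    pos = s[binary == 1]
    p_w, reject = wilcoxon_rank_sum(neg, pos)
    report.update(
        {
            "mode": "binary",
            **cls.as_dict(),
            "p_wilcoxon": p_w,
            "reject_equal_medians": reject,
            "cohens_d": cohens_d(neg, pos),
        }
    )
    return report
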
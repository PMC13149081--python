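"""Metrics and patient-level statistical inference.

Overlap and classification metrics (Dice, IoU, accuracy, sensitivity,
specificity, F1, rank-based AUC), stratified patient-level bootstrap
confidence intervals (percentile, B = 2000 by default), two-sided paired
Wilcoxon signed-rank tests (exact sign-flip null for up to 25 informative
pairs, normal approximation with continuity correction above), the
Holm-Bonferroni step-down correction, and the fold-dispersion coefficient
of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, rankdata


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class StatsConfig:
    n_boot: int = 2000
    ci_level: float = 0.95
    exact_limit: int = 25  # informative pairs up to which the Wilcoxon null is exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("need at least one bootstrap replicate")
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must be in (0, 1)")


# --------------------------------------------------------------------------- #
# mask and score metrics
# --------------------------------------------------------------------------- #


def _confusion(pred: np.ndarray, true: np.ndarray) -> tuple[float, float, float, float]:
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch between prediction and truth")
    tp = float(np.sum(pred & true))
    fp = float(np.sum(pred & ~true))
    fn = float(np.sum(~pred & true))
    tn = float(np.sum(~pred & ~true))
    return tp, fp, fn, tn


def dice(pred: np.ndarray, true: np.ndarray) -> float:
    """``2|A n B| / (|A| + |B|)``; two empty masks score 1."""
    tp, fp, fn, _ = _confusion(pred, true)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def iou(pred: np.ndarray, true: np.ndarray) -> float:
    tp, fp, fn, _ = _confusion(pred, true)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    tp, fp, fn, tn = _confusion(pred, true)
    return (tp + tn) / (tp + fp + fn + tn)


def sensitivity(pred: np.ndarray, true: np.ndarray) -> float:
    tp, _, fn, _ = _confusion(pred, true)
    if tp + fn == 0:
        raise UndefinedStatisticError("no positive ground truth")
    return tp / (tp + fn)


def specificity(pred: np.ndarray, true: np.ndarray) -> float:
    _, fp, _, tn = _confusion(pred, true)
    if tn + fp == 0:
        raise UndefinedStatisticError("no negative ground truth")
    return tn / (tn + fp)


def f1_score(pred: np.ndarray, true: np.ndarray) -> float:
    """Positive-class F1 (class 1 = mutant/methylated)."""
    tp, fp, fn, _ = _confusion(pred, true)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: the Mann-Whitney U statistic over n0*n1, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedStatisticError("both classes must be present")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# --------------------------------------------------------------------------- #
# bootstrap, Wilcoxon, Holm, CoV
# --------------------------------------------------------------------------- #


def bootstrap_ci(
    values: np.ndarray,
    strata: np.ndarray | None = None,
    config: StatsConfig | None = None,
    statistic: Callable[[np.ndarray], float] = np.mean,
) -> tuple[float, float, float]:
    """Stratified percentile bootstrap CI: ``(low, high, point estimate)``.

    Patients are resampled with replacement within each stratum and the
    statistic recomputed B times.
    """
    cfg = config or StatsConfig()
    values = np.asarray(values, float)
    if strata is None:
        strata = np.zeros(values.size, int)
    strata = np.asarray(strata)
    groups = [np.nonzero(strata == s)[0] for s in np.unique(strata)]
    for g in groups:
        if g.size < 2:
            raise ValueError("each stratum needs at least 2 patients")
    rng = np.random.default_rng(cfg.seed)
    stats = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        stats[b] = statistic(values[idx])
    a = (1.0 - cfg.ci_level) / 2.0
    low, high = np.quantile(stats, [a, 1.0 - a])
    return float(low), float(high), float(statistic(values))


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ (sum of positive signed ranks)
    n_informative: int
    exact: bool
    degenerate: bool
    delta: float  # mean paired difference A - B
    delta_ci: tuple[float, float] | None = None


def _exact_signflip_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p under the sign-flip null via convolution over doubled
    midranks (exact under ties; equals 2^n enumeration)."""
    r2 = np.round(2 * ranks).astype(int)  # midranks are half-integers
    total = int(r2.sum())
    # distribution of 2*W+ over sign assignments
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(
    a: np.ndarray,
    b: np.ndarray,
    config: StatsConfig | None = None,
    strata: np.ndarray | None = None,
    delta_ci: bool = True,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test with effect size.

    Zero differences are dropped; ties get midranks.  Exact sign-flip null
    for up to ``exact_limit`` informative pairs, otherwise normal
    approximation with continuity and tie corrections.  The mean paired
    difference (Delta) is reported with its bootstrap CI.
    """
    cfg = config or StatsConfig()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    delta = float(d.mean())
    ci = None
    if delta_ci and d.size >= 2:
        lo, hi, _ = bootstrap_ci(d, strata=strata, config=cfg)
        ci = (lo, hi)

    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, True, True, delta, ci)
    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n <= cfg.exact_limit:
        p = _exact_signflip_pvalue(ranks, w_plus)
        return WilcoxonResult(p, w_plus, n, True, False, delta, ci)
    mean = n * (n + 1) / 4.0
    # variance with tie correction over the rank multiset
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(p, w_plus, n, False, False, delta, ci)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def cov(values: Sequence[float]) -> float:
    """Coefficient of variation, ``100 * SD / mean`` (sample SD, n-1)."""
    v = np.asarray(values, float)
    mean = v.mean()
    if mean == 0:
        raise UndefinedStatisticError("zero mean")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(100.0 * sd / mean)


def segmentation_metrics(pred: np.ndarray, true: np.ndarray) -> dict[str, float]:
    return {
        "dice": dice(pred, true),
        "iou": iou(pred, true),
        "accuracy": accuracy(pred, true),
    }


def classification_metrics(
    pred_labels: np.ndarray, scores: np.ndarray, true_labels: np.ndarray
) -> dict[str, float]:
    return {
        "accuracy": accuracy(pred_labels, true_labels),
        "sensitivity": sensitivity(pred_labels, true_labels),
        "specificity": specificity(pred_labels, true_labels),
        "f1": f1_score(pred_labels, true_labels),
        "auc": auc(scores, true_labels),
    }
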
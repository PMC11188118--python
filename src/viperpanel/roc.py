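"""ROC curves, AUC with confidence intervals, and Wilson score intervals.

The empirical ROC is traced over all distinct score thresholds; its
trapezoidal area equals the Mann-Whitney statistic divided by
``n_pos * n_neg`` with ties counting one half (both routes are exposed and
agree exactly, which the test suite exploits as a self-check).  AUC
confidence intervals use the DeLong rank-based variance, falling back to a
stratified bootstrap when a class is too small for the asymptotics.
Sensitivity/specificity at an operating point get Wilson score intervals,
the binomial interval that stays inside [0, 1] (for 9/9 successes at 95% the
lower bound is n/(n + z^2) = 0.7009).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocResult",
    "OperatingPoint",
    "roc",
    "auc_rank",
    "wilson_interval",
    "operating_point",
    "delong_ci",
]


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    rule: str


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and its confidence interval."""

    thresholds: np.ndarray  # descending
    fpr: np.ndarray  # nondecreasing
    tpr: np.ndarray  # nondecreasing
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    flipped: bool = False  # score orientation reversed to reach AUC >= 0.5

    def to_frame(self):
        """Full coordinate table (threshold, fpr, tpr) for export."""
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (midranks; ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_classes(labels)
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def delong_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """AUC confidence interval: DeLong variance, bootstrap fallback.

    The fallback (stratified percentile bootstrap) kicks in when either
    class has fewer than 3 members or the DeLong variance degenerates to 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_classes(labels)
    auc = auc_rank(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    use_boot = n_pos < 3 or n_neg < 3
    if not use_boot:
        # placement values (midrank convention), vectorized
        cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        v10 = cmp.mean(axis=1)
        v01 = cmp.mean(axis=0)
        var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
        if var <= 0:
            use_boot = True
        else:
            z = norm.ppf(0.5 + level / 2.0)
            half = z * np.sqrt(var)
            return (max(0.0, auc - half), min(1.0, auc + half))
    if rng is None:
        rng = np.random.default_rng(0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, n_pos, n_pos)]
        bn = neg[rng.integers(0, n_neg, n_neg)]
        stats[b] = auc_rank(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
        )
    lo, hi = np.quantile(stats, [(1 - level) / 2.0, 0.5 + level / 2.0])
    return (float(lo), float(hi))


def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    auto_orient: bool = False,
    rng: np.random.Generator | None = None,
    ci: bool = True,
) -> RocResult:
    """Empirical ROC over all distinct thresholds, trapezoidal AUC.

    ``labels`` is boolean with True = positive class (here: deceased).
    With ``auto_orient`` the score sign is flipped when AUC < 0.5 and the
    flip recorded, so "low score = high risk" markers evaluate naturally.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_classes(labels)
    flipped = False
    if auto_orient and auc_rank(scores, labels) < 0.5:
        scores = -scores
        flipped = True
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    interval = (
        delong_ci(scores, labels, level=level, rng=rng)
        if ci else (float("nan"), float("nan"))
    )
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_ci=interval,
        n_pos=n_pos,
        n_neg=n_neg,
        flipped=flipped,
    )


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # boundary cases are exact analytically; snap away float residue
    lo = 0.0 if successes == 0 else max(0.0, float(lo))
    hi = 1.0 if successes == n else min(1.0, float(hi))
    return float(lo), float(hi)


def operating_point(result: RocResult, rule: str = "youden") -> OperatingPoint:
    """Pick a threshold and report sensitivity/specificity with Wilson CIs.

    ``youden`` maximizes TPR - FPR; ``max_sens_then_spec`` takes, among
    thresholds of maximal sensitivity, the one with maximal specificity.
    Ties resolve to the lower threshold.
    """
    sens = result.tpr
    spec = 1.0 - result.fpr
    if rule == "youden":
        crit = sens - result.fpr  # Youden J
    elif rule == "max_sens_then_spec":
        crit = np.where(sens == sens.max(), spec, -np.inf)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    # thresholds descend, so the *last* argmax is the lowest threshold
    best = np.flatnonzero(crit == crit.max())[-1]
    s, sp = float(sens[best]), float(spec[best])
    sens_ci = wilson_interval(int(round(s * result.n_pos)), result.n_pos)
    spec_ci = wilson_interval(int(round(sp * result.n_neg)), result.n_neg)
    return OperatingPoint(
        threshold=float(result.thresholds[best]),
        sensitivity=s,
        specificity=sp,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        rule=rule,
    )
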
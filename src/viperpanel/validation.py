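"""Self-validation studies: estimator calibration against known truth.

Each function runs a simulation study that checks one pillar of the
pipeline against an analytic limit or the generator's ground truth:

* the Tobit fitter collapses to OLS when nothing is censored;
* under left-censoring it recovers the true effect with negligible bias and
  nominal Wald coverage;
* the directional-FDR procedure keeps the false discovery proportion at its
  nominal level under a global null;
* trapezoidal and rank-statistic AUCs coincide;
* the end-to-end derivation recovers the cohort's embedded survival panel.

These studies are what the acceptance script reports and what the
acceptance tests assert, so they are part of the package proper rather than
test scaffolding.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import pipeline
from .importance import permutation_importance
from .roc import auc_rank, roc
from .synthetic import VIPER_PANEL, default_paperlike_config, generate
from .tobit import directional_fdr, tobit_fit

__all__ = [
    "ols_limit_max_rel_diff",
    "tobit_recovery_study",
    "null_fdp_study",
    "auc_equivalence_study",
    "importance_normalization_check",
    "panel_recovery_study",
]


def ols_limit_max_rel_diff(seed: int = 0, n: int = 500) -> float:
    """Max relative difference between Tobit and OLS with zero censoring."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = X @ np.array([0.8, -0.5, 0.3]) + 0.7 * rng.normal(size=n)
    fit = tobit_fit(y, X, np.zeros(n, dtype=bool))
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma_ols = math.sqrt(float(np.mean((y - X @ beta_ols) ** 2)))
    rel_beta = np.abs(fit.beta - beta_ols) / np.maximum(np.abs(beta_ols), 1e-12)
    rel_sigma = abs(fit.sigma - sigma_ols) / sigma_ols
    return float(max(rel_beta.max(), rel_sigma))


def _one_tobit_replicate(rng, n, effect, sigma, censor_frac):
    half = n // 2
    group = np.zeros(n)
    group[half:] = 1.0
    X = np.column_stack([np.ones(n), group])
    ystar = 2.0 + effect * group + sigma * rng.normal(size=n)
    c = np.quantile(ystar, censor_frac) if censor_frac > 0 else -np.inf
    cens = ystar < c
    y = np.where(cens, c, ystar)
    return tobit_fit(y, X, cens)


def tobit_recovery_study(
    n_reps: int = 200,
    n: int = 1000,
    effect: float = math.log(1.231),
    sigma: float = 0.5,
    censor_frac: float = 0.3,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Bias and Wald-CI coverage of the group effect under 30% censoring."""
    rng = np.random.default_rng(seed)
    z = norm.ppf(0.5 + level / 2.0)
    errors, covered = [], []
    for _ in range(n_reps):
        fit = _one_tobit_replicate(rng, n, effect, sigma, censor_frac)
        errors.append(fit.beta[1] - effect)
        covered.append(abs(fit.beta[1] - effect) <= z * fit.se[1])
    return {
        "mean_bias": float(np.mean(errors)),
        "mean_abs_bias": float(abs(np.mean(errors))),
        "coverage_pct": float(np.mean(covered) * 100.0),
        "n_reps": n_reps,
        "n": n,
    }


def null_fdp_study(
    n_sims: int = 500,
    n_analytes: int = 59,
    n_per_group: int = 60,
    censor_frac: float = 0.3,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Mean false discovery proportion under a global null.

    Each simulation fits one Tobit model per analyte on null two-group data
    (no effect, ~30% left-censoring at a fixed threshold) and applies the
    directional FDR at ``alpha``; every discovery is false, so the FDP is
    the fraction of analytes declared significant when any are.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.zeros(n)
    group[n_per_group:] = 1.0
    X = np.column_stack([np.ones(n), group])
    c = norm.ppf(censor_frac)  # fixed threshold on the N(0,1) scale
    fdps = []
    for _ in range(n_sims):
        fits = []
        for j in range(n_analytes):
            ystar = rng.normal(size=n)
            cens = ystar < c
            y = np.where(cens, c, ystar)
            fits.append(
                tobit_fit(y, X, cens, predictors=["intercept", "trauma"],
                          analyte=f"a{j}")
            )
        directional_fdr(fits, alpha=alpha)
        n_disc = sum(bool(f.significant[1]) for f in fits)
        fdps.append(1.0 if n_disc > 0 else 0.0)  # all discoveries are false
    return {
        "mean_fdp": float(np.mean(fdps)),
        "n_sims": n_sims,
        "n_analytes": n_analytes,
    }


def auc_equivalence_study(n_instances: int = 1000, seed: int = 0) -> dict:
    """Trapezoid-vs-rank AUC agreement over random tied-score instances,
    plus the enumerable toy case positives {3, 5} vs negatives {1, 4}."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 60))
        scores = rng.integers(0, 8, size=n).astype(float)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        max_diff = max(
            max_diff,
            abs(roc(scores, labels, ci=False).auc - auc_rank(scores, labels)),
        )
    toy = roc(
        np.array([3.0, 5.0, 1.0, 4.0]), np.array([True, True, False, False])
    ).auc
    return {"max_abs_diff": float(max_diff), "toy_auc": float(toy), "n": n_instances}


def importance_normalization_check(seed: int = 0) -> float:
    """Max per-iteration relative importance on a small signal problem
    (must be exactly 100 in every iteration)."""
    rng = np.random.default_rng(seed)
    n = 200
    y = rng.random(n) < 0.5
    X = pd.DataFrame(
        {
            "signal": rng.normal(size=n) + 1.5 * y,
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        }
    )
    result = permutation_importance(X, y, n_iterations=5, n_trees=50, seed=seed)
    return float(np.min(result.relative.max(axis=0)))


def panel_recovery_study(n_seeds: int = 20, seed: int = 0, cv_folds: int = 5) -> dict:
    """End-to-end derivation on fresh default cohorts.

    For each cohort seed: generate the default study-like cohort, run the
    full candidate funnel, check whether the final panel equals the five
    embedded outcome-linked analytes, and measure the cross-validated AUC
    of the score fit on the embedded panel.
    """
    recovered, cv_aucs, panels = [], [], []
    for k in range(n_seeds):
        cohort_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))
        panel, subjects, _ = generate(default_paperlike_config(seed=cohort_seed))
        derivation = pipeline.derive_panel(panel, subjects, seed=cohort_seed)
        recovered.append(set(derivation.final_panel) == set(VIPER_PANEL))
        model = pipeline.fit_viper(panel, subjects, list(VIPER_PANEL), seed=cohort_seed)
        rocs = pipeline.evaluate_by_level(
            model, panel, subjects, strata=("all",), method="cv",
            n_splits=cv_folds, seed=cohort_seed,
        )
        cv_aucs.append(rocs["all"].auc)
        panels.append(sorted(derivation.final_panel))
    return {
        "recovery_pct": float(np.mean(recovered) * 100.0),
        "mean_cv_auc": float(np.mean(cv_aucs)),
        "min_cv_auc": float(np.min(cv_aucs)),
        "n_seeds": n_seeds,
        "panels": panels,
    }
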
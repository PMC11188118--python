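"""Left-censored Gaussian (Tobit) regression with directional FDR.

Immunoassay concentrations below the lower LOD are left-censored at a known
threshold, so ordinary least squares on substituted values is biased.  The
Tobit model assumes

    y_i* = x_i' beta + sigma * eps_i,   eps ~ N(0, 1)
    y_i  = y_i*          if y_i* >= c_i      (observed)
    y_i  = "< c_i"       otherwise           (left-censored at c_i)

and maximizes the censored-Gaussian log-likelihood

    sum_obs  [ log phi((y_i - x_i'beta)/sigma) - log sigma ]
  + sum_cens [ log Phi((c_i - x_i'beta)/sigma) ]

over (beta, log sigma) by quasi-Newton with an analytic gradient, starting
from OLS on threshold-substituted values.  Wald confidence intervals come
from the observed information (numerical Hessian of the negative
log-likelihood at the optimum).  Here y is a natural-log concentration and
c = log(lower LOD), so a coefficient beta reports as a multiplicative
concentration change: percent change = (e**beta - 1) * 100.

Significance uses *directional* q-values: one-sided Wald p-values toward
each direction, Benjamini-Hochberg adjusted separately within the positive
and the negative family across analytes.  An association is declared
significant when its smaller directional q-value falls below alpha/2, which
controls the overall directional FDR at alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests

from .panel_io import (
    BELOW,
    MISSING,
    PanelMatrix,
    ProcessedPanel,
    SubjectRecord,
)

__all__ = [
    "TobitFit",
    "LodPrevalence",
    "tobit_fit",
    "percent_change",
    "fit_panel",
    "directional_fdr",
    "lod_prevalence_compare",
    "results_frame",
]

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class AllCensoredError(ValueError):
    """Every observation is censored; beta and sigma are not identifiable."""


@dataclass
class TobitFit:
    """Maximum-likelihood censored-regression fit for one analyte."""

    analyte: str
    predictors: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma: float
    sigma_se: float
    cov: np.ndarray  # covariance of beta
    loglik: float
    converged: bool
    n_obs: int
    n_censored: int
    # directional FDR annotations (per predictor; NaN for the intercept)
    q_pos: np.ndarray | None = None
    q_neg: np.ndarray | None = None
    significant: np.ndarray | None = None
    direction: list[str] | None = None

    def percent_change(self, level: float = 0.95) -> pd.DataFrame:
        """Coefficients as percent concentration change with Wald CIs."""
        rows = [
            percent_change(b, s, level=level)
            for b, s in zip(self.beta, self.se)
        ]
        return pd.DataFrame(
            rows, columns=["percent", "lo", "hi"], index=self.predictors
        )

    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se


def _nll_and_grad(theta, X, y, cens, cens_right=None):
    """Negative log-likelihood and gradient in (beta, log sigma).

    ``y`` holds the measurement at observed rows and the censoring
    threshold at censored rows (left at c = log lower LOD; right, when
    enabled, at the upper threshold).
    """
    p = X.shape[1]
    beta, log_s = theta[:p], theta[p]
    with np.errstate(over="ignore", invalid="ignore"):
        s = np.exp(log_s)
        resid = y - X @ beta
        scaled = resid / s
    if not np.all(np.isfinite(scaled)):
        # diverged line-search trial point: reject without poisoning gradients
        return np.inf, np.zeros(p + 1)
    if cens_right is None:
        cens_right = np.zeros_like(cens)
    obs = ~cens & ~cens_right
    r = resid[obs] / s
    nll = 0.5 * np.dot(r, r) + obs.sum() * (log_s + _LOG_SQRT_2PI)
    g_beta = -(X[obs].T @ r) / s
    g_logs = obs.sum() - np.dot(r, r)
    if cens.any():
        u = resid[cens] / s  # (c - x'beta)/sigma
        log_cdf = log_ndtr(u)
        nll -= log_cdf.sum()
        # phi/Phi, clipped: the exponent grows only like log|u|, so the cap
        # is reachable only from absurd trial points already rejected above
        lam = np.exp(np.minimum(-0.5 * u * u - _LOG_SQRT_2PI - log_cdf, 700.0))
        g_beta += (X[cens].T @ lam) / s
        g_logs += np.dot(lam, u)
    if cens_right.any():
        v = -resid[cens_right] / s  # (x'beta - c)/sigma; P(Y > c) = Phi(v)
        log_cdf = log_ndtr(v)
        nll -= log_cdf.sum()
        lam = np.exp(np.minimum(-0.5 * v * v - _LOG_SQRT_2PI - log_cdf, 700.0))
        g_beta -= (X[cens_right].T @ lam) / s
        g_logs += np.dot(lam, v)
    grad = np.empty(p + 1)
    grad[:p] = g_beta
    grad[p] = g_logs
    return nll, grad


def _numerical_hessian(theta, X, y, cens, cens_right=None, rel_step=1e-5):
    """Observed information via central differences of the analytic gradient."""
    m = theta.size
    H = np.empty((m, m))
    for i in range(m):
        h = rel_step * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _nll_and_grad(tp, X, y, cens, cens_right)
        _, gm = _nll_and_grad(tm, X, y, cens, cens_right)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def tobit_fit(
    y: np.ndarray,
    X: np.ndarray,
    censored: np.ndarray,
    predictors: list[str] | None = None,
    analyte: str = "",
    gtol: float = 1e-8,
    max_iter: int = 300,
    censored_right: np.ndarray | None = None,
) -> TobitFit:
    """Fit a left-censored Gaussian regression by maximum likelihood.

    Parameters
    ----------
    y
        Response vector; at censored entries it must hold the censoring
        threshold (here log lower LOD), at observed entries the measurement.
    X
        Design matrix including the intercept column; must be full rank.
    censored
        Boolean left-censoring flags aligned with ``y``.
    censored_right
        Optional right-censoring flags (off by default; the standard
        preprocessing treats above-LOD cells as observed at upper*1.1).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    censored = np.asarray(censored, dtype=bool)
    n, p = X.shape
    if censored_right is None:
        censored_right = np.zeros(n, dtype=bool)
    censored_right = np.asarray(censored_right, dtype=bool)
    if y.shape != (n,) or censored.shape != (n,) or censored_right.shape != (n,):
        raise ValueError("y, X, censored have inconsistent shapes")
    if (censored & censored_right).any():
        raise ValueError("a row cannot be censored in both directions")
    if not (~censored & ~censored_right).any():
        raise AllCensoredError(
            f"analyte {analyte!r}: all observations censored; model not identifiable"
        )
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"analyte {analyte!r}: design matrix is rank deficient")
    if predictors is None:
        predictors = [f"x{i}" for i in range(p)]

    # OLS on threshold-substituted values as a starting point.
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    s0 = max(float(np.sqrt(np.mean(resid0**2))), 1e-3)
    theta0 = np.concatenate([beta0, [np.log(s0)]])
    nll0, _ = _nll_and_grad(theta0, X, y, censored, censored_right)

    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(X, y, censored, censored_right),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    _, grad = _nll_and_grad(res.x, X, y, censored, censored_right)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-6 * (
        1.0 + abs(res.fun)
    )
    if not converged:
        warnings.warn(
            f"tobit fit for {analyte!r} did not converge "
            f"(max |grad| = {np.max(np.abs(grad)):.3g})"
        )
    if res.fun > nll0 + 1e-8:  # defensive: optimizer must not go uphill
        res.x, res.fun = theta0, nll0

    theta = res.x
    sigma = float(np.exp(theta[-1]))
    H = _numerical_hessian(theta, X, y, censored, censored_right)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov_beta = cov_all[:p, :p]
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, np.inf))
    sigma_se = float(np.sqrt(max(cov_all[p, p], 0.0)) * sigma)  # delta method
    return TobitFit(
        analyte=analyte,
        predictors=list(predictors),
        beta=theta[:p].copy(),
        se=se,
        sigma=sigma,
        sigma_se=sigma_se,
        cov=cov_beta,
        loglik=-float(res.fun),
        converged=converged,
        n_obs=int((~censored & ~censored_right).sum()),
        n_censored=int(censored.sum() + censored_right.sum()),
    )


def percent_change(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Map a log-scale coefficient to percent concentration change with CI.

    point = (e**beta - 1) * 100; endpoints use beta +/- z * se.
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    z = norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):  # an unbounded CI end maps to inf%
        point = (np.exp(beta) - 1.0) * 100.0
        lo = (np.exp(beta - z * se) - 1.0) * 100.0
        hi = (np.exp(beta + z * se) - 1.0) * 100.0
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Panel-level model fitting
# ---------------------------------------------------------------------------


def _location_category(s: SubjectRecord) -> str | None:
    locs = set(s.locations) - {"unknown"}
    if not locs or "unknown" in s.locations:
        return None
    if locs == {"head_neck", "torso", "peripheral"}:
        return "all"
    if len(locs) == 2:
        return "combination"
    return next(iter(locs))


def _wound_category(s: SubjectRecord) -> str | None:
    if not s.wound_type:
        return None
    return "+".join(sorted(s.wound_type))


def design_matrix(
    subjects: list[SubjectRecord], model: str
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build (X, term names, subject mask) for a panel-wide model.

    Categorical predictors are one-hot encoded against fixed reference
    levels (control; trauma level 4; mechanism "other"; location
    "peripheral"; wound "soft_tissue"; covid "negative") so coefficient
    signs are reproducible across runs.
    """
    n = len(subjects)
    trauma = np.array([s.group == "trauma" for s in subjects], dtype=float)
    if model == "univariable_group":
        X = np.column_stack([np.ones(n), trauma])
        return X, ["intercept", "trauma"], np.ones(n, dtype=bool)
    if model == "age_adjusted":
        age = np.array([s.age for s in subjects])
        X = np.column_stack([np.ones(n), trauma, age - age.mean()])
        return X, ["intercept", "trauma", "age"], np.ones(n, dtype=bool)
    if model in ("sex_adjusted", "sex_interaction"):
        mask = np.array([s.sex in ("female", "male") for s in subjects])
        female = np.array([s.sex == "female" for s in subjects], dtype=float)
        cols = [np.ones(n), trauma, female]
        names = ["intercept", "trauma", "female"]
        if model == "sex_interaction":
            cols.append(female * trauma)
            names.append("female:trauma")
        X = np.column_stack(cols)
        return X[mask], names, mask

    categorical: dict[str, tuple] = {
        # model -> (per-subject category, reference level, trauma only?)
        "trauma_level": (
            lambda s: None if s.trauma_level is None else f"level_{s.trauma_level}",
            "level_4",
        ),
        "mechanism": (
            lambda s: None if s.mechanism == "unknown" else s.mechanism,
            "other",
        ),
        "location": (_location_category, "peripheral"),
        "wound_type": (_wound_category, "soft_tissue"),
        "covid": (
            lambda s: s.covid if s.covid in ("positive", "negative") else None,
            "negative",
        ),
    }
    if model not in categorical:
        raise ValueError(f"unknown model {model!r}")
    get_cat, ref = categorical[model]
    cats = [get_cat(s) if s.group == "trauma" else None for s in subjects]
    mask = np.array([c is not None for c in cats])
    levels = sorted({c for c in cats if c is not None and c != ref})
    kept = [c for c in cats if c is not None]
    if ref not in kept:
        raise ValueError(f"model {model!r}: reference level {ref!r} absent")
    cols = [np.ones(len(kept))]
    names = ["intercept"]
    for lev in levels:
        cols.append(np.array([float(c == lev) for c in kept]))
        names.append(f"{model}[{lev}]")
    return np.column_stack(cols), names, mask


def fit_panel(
    processed: ProcessedPanel,
    subjects: list[SubjectRecord],
    model: str = "univariable_group",
) -> list[TobitFit]:
    """One Tobit fit per analyte under the requested model.

    Analytes whose usable cells are all censored (or fewer cells than
    parameters) are skipped with a logged reason.  ``processed`` must be in
    analysis mode.
    """
    if processed.mode != "analysis":
        raise ValueError("fit_panel requires an analysis-mode ProcessedPanel")
    X_full, names, mask = design_matrix(subjects, model)
    fits: list[TobitFit] = []
    for j, a in enumerate(processed.analytes):
        y = processed.log_conc[mask, j]
        cens = processed.censor_left[mask, j]
        usable = np.isfinite(y)
        y, cens, X = y[usable], cens[usable], X_full[usable]
        if y.size <= X_full.shape[1] or not (~cens).any():
            logger.info(
                "skipping analyte %s under model %s: %d usable cells, %d censored",
                a.name, model, y.size, int(cens.sum()),
            )
            continue
        try:
            fits.append(
                tobit_fit(y, X, cens, predictors=names, analyte=a.name)
            )
        except (AllCensoredError, ValueError) as exc:
            logger.info("skipping analyte %s under model %s: %s", a.name, model, exc)
    return fits


def _storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey's null-fraction estimate at a fixed lambda, capped at 1."""
    return min(1.0, float((pvals > lam).mean() / (1.0 - lam)))


def directional_fdr(
    fits: list[TobitFit], alpha: float = 0.01, pi0: str = "fixed"
) -> list[TobitFit]:
    """Annotate fits with directional Benjamini-Hochberg q-values.

    For each non-intercept term, one-sided Wald p-values toward the positive
    and the negative direction are adjusted separately (BH within each
    directional family, across analytes, per term).  A term is significant
    when min(q_pos, q_neg) < alpha/2, controlling the overall directional
    FDR at alpha.  With ``pi0="storey"`` each family's q-values are scaled
    by Storey's estimated null fraction (lambda = 0.5) for extra power when
    many analytes carry real effects; the default keeps pi0 = 1.
    """
    if not fits:
        raise ValueError("no fits to adjust")
    if pi0 not in ("fixed", "storey"):
        raise ValueError(f"unknown pi0 method {pi0!r}")
    terms = fits[0].predictors
    for f in fits:
        f.q_pos = np.full(len(f.predictors), np.nan)
        f.q_neg = np.full(len(f.predictors), np.nan)
        f.significant = np.zeros(len(f.predictors), dtype=bool)
        f.direction = ["" for _ in f.predictors]
    for t_idx, term in enumerate(terms):
        if term == "intercept":
            continue
        members = [f for f in fits if t_idx < len(f.predictors)]
        z = np.array([f.wald_z()[t_idx] for f in members])
        ok = np.isfinite(z)
        if not ok.any():
            continue
        p_pos = norm.sf(z[ok])  # H1: beta > 0
        p_neg = norm.cdf(z[ok])  # H1: beta < 0
        q_pos = multipletests(p_pos, method="fdr_bh")[1]
        q_neg = multipletests(p_neg, method="fdr_bh")[1]
        if pi0 == "storey":
            q_pos = np.minimum(q_pos * _storey_pi0(p_pos), 1.0)
            q_neg = np.minimum(q_neg * _storey_pi0(p_neg), 1.0)
        for f, qp, qn in zip([m for m, o in zip(members, ok) if o], q_pos, q_neg):
            f.q_pos[t_idx] = qp
            f.q_neg[t_idx] = qn
            if min(qp, qn) < alpha / 2.0:
                f.significant[t_idx] = True
                f.direction[t_idx] = "positive" if qp < qn else "negative"
    return fits


def results_frame(fits: list[TobitFit], model: str = "") -> pd.DataFrame:
    """Tidy per-term results table (one row per analyte x non-intercept term)."""
    rows = []
    for f in fits:
        for i, term in enumerate(f.predictors):
            if term == "intercept":
                continue
            pct, lo, hi = percent_change(f.beta[i], f.se[i])
            rows.append(
                {
                    "analyte": f.analyte,
                    "model": model,
                    "term": term,
                    "beta": f.beta[i],
                    "se": f.se[i],
                    "percent_change": pct,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "q_pos": f.q_pos[i] if f.q_pos is not None else np.nan,
                    "q_neg": f.q_neg[i] if f.q_neg is not None else np.nan,
                    "significant": bool(f.significant[i]) if f.significant is not None else False,
                    "direction": f.direction[i] if f.direction is not None else "",
                    "converged": f.converged,
                    "n_obs": f.n_obs,
                    "n_censored": f.n_censored,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Below-LOD prevalence
# ---------------------------------------------------------------------------


@dataclass
class LodPrevalence:
    """Trauma-vs-control comparison of the below-LOD fraction for one analyte."""

    analyte: str
    frac_below_trauma: float
    frac_below_control: float
    difference: float  # percentage points, trauma minus control
    p_value: float
    q_value: float = np.nan
    n_trauma: int = 0
    n_control: int = 0


def lod_prevalence_compare(
    panel: PanelMatrix, subjects: list[SubjectRecord]
) -> list[LodPrevalence]:
    """Exact conditional (Fisher) test of below-LOD prevalence per analyte.

    Builds the 2x2 table (below vs detected) x (trauma vs control) over
    non-missing cells and BH-adjusts the two-sided p-values across analytes.
    """
    trauma = np.array([s.group == "trauma" for s in subjects])
    if not trauma.any() or trauma.all():
        raise ValueError("need both trauma and control subjects")
    results: list[LodPrevalence] = []
    for j, a in enumerate(panel.analytes):
        st = panel.status[:, j]
        present = st != MISSING
        if not (present & trauma).any() or not (present & ~trauma).any():
            warnings.warn(f"analyte {a.name!r} absent in one group; skipped")
            continue
        below = st == BELOW
        bt = int((below & trauma).sum())
        nt = int((present & trauma).sum())
        bc = int((below & ~trauma).sum())
        nc = int((present & ~trauma).sum())
        _, p = fisher_exact([[bt, nt - bt], [bc, nc - bc]], alternative="two-sided")
        ft, fc = bt / nt, bc / nc
        results.append(
            LodPrevalence(
                analyte=a.name,
                frac_below_trauma=ft,
                frac_below_control=fc,
                difference=(ft - fc) * 100.0,
                p_value=float(p),
                n_trauma=nt,
                n_control=nc,
            )
        )
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results
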
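"""All-pairs analyte-ratio screening for survival signal.

Concentration ratios (pg/mL : pg/mL) cancel shared scale and can separate
outcome groups more sharply than either analyte alone — the motivating
example being a low IL-29:IL-10 ratio flagging high-risk patients among
less severe traumas.  This module computes per-subject ratios on ratio-mode
substituted concentrations, screens all ordered analyte pairs by the fold
change of the group-summary ratio between deceased and discharged-home
subjects, and evaluates a chosen pair as a continuous ROC predictor.

Group summaries are medians computed on the log scale (equal to the median
ratio for odd group sizes); this makes the fold-change matrix exactly
antisymmetric on the log scale, pair by pair.  Subjects discharged anywhere
other than home are excluded from all outcome contrasts, as are controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import ProcessedPanel, SubjectRecord
from .roc import RocResult, roc

__all__ = ["RatioTable", "compute_ratio", "fold_change_matrix", "ratio_predictor_eval", "outcome_mask"]


def outcome_mask(
    subjects: list[SubjectRecord],
    trauma_level: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(usable, deceased) masks for the discharged-home vs deceased contrast.

    Keeps trauma subjects whose outcome is ``discharged_home`` or
    ``deceased`` (optionally restricted to one trauma activation level);
    every other disposition is excluded.
    """
    usable = np.array(
        [
            s.group == "trauma"
            and s.outcome in ("discharged_home", "deceased")
            and (trauma_level is None or s.trauma_level == trauma_level)
            for s in subjects
        ]
    )
    deceased = np.array([s.outcome == "deceased" for s in subjects])
    return usable, deceased & usable


@dataclass
class RatioTable:
    """Fold changes of pairwise ratio summaries between two outcome groups.

    ``fold.loc[a, b]`` is summary(ratio a/b in group_a) over
    summary(ratio a/b in group_b); ``log(fold)`` is antisymmetric in (a, b).
    """

    analytes: list[str]
    fold: pd.DataFrame  # k x k, NaN on the diagonal
    log_fold: pd.DataFrame  # exact antisymmetric log-scale matrix
    n_group_a: int
    n_group_b: int
    summary: str = "median"

    def pairs(self) -> pd.DataFrame:
        """Tidy ordered-pair table ranked by |log fold| (descending)."""
        rows = []
        k = len(self.analytes)
        values = self.log_fold.to_numpy()
        for i in range(k):
            for j in range(k):
                if i == j or not np.isfinite(values[i, j]):
                    continue
                rows.append(
                    {
                        "numerator": self.analytes[i],
                        "denominator": self.analytes[j],
                        "fold": np.exp(values[i, j]),
                        "log_fold": values[i, j],
                    }
                )
        out = pd.DataFrame(rows)
        if not out.empty:
            out = out.reindex(
                out["log_fold"].abs().sort_values(ascending=False).index
            ).reset_index(drop=True)
            out["rank"] = np.arange(1, len(out) + 1)
        return out

    def top_analytes(self, n_pairs: int) -> list[str]:
        """Analytes appearing among the ``n_pairs`` largest |log fold| pairs."""
        top = self.pairs().head(n_pairs)
        seen: list[str] = []
        for _, row in top.iterrows():
            for name in (row["numerator"], row["denominator"]):
                if name not in seen:
                    seen.append(name)
        return seen


def compute_ratio(
    processed: ProcessedPanel, numerator: str, denominator: str
) -> pd.Series:
    """Per-subject concentration ratio numerator/denominator (dimensionless).

    Requires a ratio-mode panel (below-LOD cells already substituted).
    Subjects missing either analyte are excluded.
    """
    if processed.mode != "ratio":
        raise ValueError("compute_ratio requires a ratio-mode ProcessedPanel")
    names = processed.analyte_names
    for name in (numerator, denominator):
        if name not in names:
            raise KeyError(f"analyte {name!r} not in panel")
    num = processed.conc[:, names.index(numerator)]
    den = processed.conc[:, names.index(denominator)]
    ok = np.isfinite(num) & np.isfinite(den)
    if np.any(den[ok] <= 0):
        raise ValueError(f"denominator {denominator!r} has a substitute <= 0")
    return pd.Series(
        num[ok] / den[ok],
        index=[s for s, keep in zip(processed.subject_ids, ok) if keep],
        name=f"{numerator}:{denominator}",
    )


def _log_summary(log_ratios: np.ndarray, summary: str) -> np.ndarray:
    """Summarize per-subject log ratios over axis 0, ignoring NaNs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        if summary == "median":
            return np.nanmedian(log_ratios, axis=0)
        if summary == "geometric_mean":
            return np.nanmean(log_ratios, axis=0)
    raise ValueError(f"unknown summary {summary!r}")


def fold_change_matrix(
    processed: ProcessedPanel,
    subjects: list[SubjectRecord],
    group_a: str = "deceased",
    group_b: str = "discharged_home",
    summary: str = "median",
) -> RatioTable:
    """Fold change of every ordered pair's summary ratio, group_a vs group_b.

    Works on log concentrations: per subject, log ratio(i, j) =
    log c_i - log c_j; the group summary (median by default) is taken on the
    log scale and exponentiated, so log-fold antisymmetry is exact.
    """
    if processed.mode != "ratio":
        raise ValueError("fold_change_matrix requires a ratio-mode ProcessedPanel")
    if summary not in ("median", "geometric_mean"):
        raise ValueError(f"unknown summary {summary!r}")
    outcomes = np.array([s.outcome for s in subjects])
    in_a = outcomes == group_a
    in_b = outcomes == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"outcome group empty: {group_a if not in_a.any() else group_b}")

    L = processed.log_conc  # (n, k)
    k = L.shape[1]

    def summary_matrix(mask: np.ndarray) -> np.ndarray:
        sub = L[mask]
        diff = sub[:, :, None] - sub[:, None, :]  # (n_g, k, k) log ratios
        return _log_summary(diff, summary)

    log_fold = summary_matrix(in_a) - summary_matrix(in_b)
    np.fill_diagonal(log_fold, np.nan)
    fold = np.exp(log_fold)
    names = processed.analyte_names
    return RatioTable(
        analytes=names,
        fold=pd.DataFrame(fold, index=names, columns=names),
        log_fold=pd.DataFrame(log_fold, index=names, columns=names),
        n_group_a=int(in_a.sum()),
        n_group_b=int(in_b.sum()),
        summary=summary,
    )


def ratio_predictor_eval(
    processed: ProcessedPanel,
    subjects: list[SubjectRecord],
    numerator: str,
    denominator: str,
    trauma_level: int | None = None,
    rng: np.random.Generator | None = None,
) -> RocResult:
    """ROC of a two-analyte ratio as a mortality predictor.

    Restricts to discharged-home vs deceased subjects (optionally within one
    trauma level), scores each by the concentration ratio, and orients the
    score so AUC >= 0.5 (``flipped`` records when low ratio = high risk).
    """
    usable, deceased = outcome_mask(subjects, trauma_level=trauma_level)
    where = "overall" if trauma_level is None else f"trauma level {trauma_level}"
    if not deceased[usable].any() or deceased[usable].all():
        raise ValueError(f"an outcome class is empty in stratum: {where}")
    ratio = compute_ratio(processed.subset(usable), numerator, denominator)
    # compute_ratio may drop subjects missing either analyte
    deceased_ids = {s.id for s in subjects if s.outcome == "deceased"}
    labels = np.array([sid in deceased_ids for sid in ratio.index])
    if not labels.any() or labels.all():
        raise ValueError(f"an outcome class is empty in stratum: {where}")
    return roc(ratio.to_numpy(), labels, auto_orient=True, rng=rng)
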
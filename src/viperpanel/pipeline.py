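"""Derivation and evaluation of the five-analyte survival score (VIPER).

VIPER ("Vital Injury Protein Evaluation for Recovery") condenses a multiplex
panel into a small algebraic risk score for in-hospital death after trauma.
The derivation reproduced here:

1. screen all analyte-ratio pairs for deceased-vs-discharged fold change;
2. rank analytes by random-forest permutation importance on the same
   contrast;
3. intersect the two candidate lists;
4. evaluate each candidate alone by ROC and prune the weakest until five
   analytes remain (default panel: IL-6, VEGF-A, IL-10, IL-29, IL-21).

The default score form is a logistic model linear in the five log
concentrations (ratio-mode LOD substitution), fit by maximum likelihood;
a ``custom_expression`` slot evaluates a user-supplied formula instead of
fitting, for transcribing an externally published equation.  Evaluation is
by ROC per trauma-level stratum, using stratified cross-validated
(out-of-sample) scores by default so the rare deceased class is preserved
in every fold.

All scoring contrasts dichotomize discharge outcome as discharged-home vs
deceased; subjects with any other disposition are excluded.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import panel_io
from .panel_io import PanelMatrix, SubjectRecord, apply_lod_rules
from .importance import feature_matrix, permutation_importance, select_features
from .ratios import fold_change_matrix, outcome_mask
from .roc import RocResult, roc
from .tobit import directional_fdr, fit_panel, lod_prevalence_compare, results_frame
from .synthetic import default_paperlike_config, generate

__all__ = [
    "PanelDerivation",
    "ViperModel",
    "derive_panel",
    "fit_viper",
    "viper_score",
    "evaluate_by_level",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_PANEL_SIZE = 5


@dataclass
class PanelDerivation:
    """Trace of the candidate funnel from screens to the final panel."""

    ratio_candidates: list[str]
    importance_candidates: list[str]
    intersection: list[str]
    per_analyte_auc: dict[str, tuple[float, float, float]]  # auc, ci_lo, ci_hi
    final_panel: list[str]


@dataclass
class ViperModel:
    """Fitted (or transcribed) survival score over a small analyte panel."""

    analytes: list[str]
    form: str  # "logistic_linear_on_logs" or "custom_expression"
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    expression_text: str | None = None
    training_meta: dict = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


def _sanitize(name: str) -> str:
    out = "".join(c if c.isalnum() else "_" for c in name)
    return "v_" + out if out[0].isdigit() else out


def _log_panel_values(
    panel: PanelMatrix, analytes: list[str]
) -> pd.DataFrame:
    """Log ratio-mode concentrations for the requested analytes."""
    processed = apply_lod_rules(panel, mode="ratio")
    frame = processed.log_frame()
    missing = [a for a in analytes if a not in frame.columns]
    if missing:
        raise KeyError(f"analytes not in panel: {missing}")
    return frame[analytes]


def derive_panel(
    panel: PanelMatrix,
    subjects: list[SubjectRecord],
    n_top_pairs: int = 30,
    importance_threshold: float = 10.0,
    panel_size: int = DEFAULT_PANEL_SIZE,
    n_trees: int = 200,
    n_iterations: int = 10,
    n_repeats: int = 3,
    seed: int = 0,
) -> PanelDerivation:
    """Run the candidate funnel on the deceased-vs-discharged contrast.

    Stage 1 collects analytes from the ``n_top_pairs`` largest |log fold|
    ratio pairs; stage 2 selects analytes with median relative permutation
    importance above ``importance_threshold``; stage 3 intersects them;
    stage 4 ranks the intersection by single-analyte AUC (DeLong CI width
    breaking ties) and keeps the best ``panel_size``.
    """
    usable, deceased = outcome_mask(subjects)
    if not deceased.any() or deceased[usable].all():
        raise ValueError("need both deceased and discharged-home subjects")
    sub_panel = panel.subset(usable)
    sub_subjects = [s for s, keep in zip(subjects, usable) if keep]
    labels = np.array([s.outcome == "deceased" for s in sub_subjects])

    # stage 1: ratio screen
    ratio_panel = apply_lod_rules(sub_panel, mode="ratio")
    table = fold_change_matrix(ratio_panel, sub_subjects)
    ratio_candidates = table.top_analytes(n_top_pairs)

    # stage 2: permutation importance (analytes only — covariates are not
    # panel candidates)
    display_panel = apply_lod_rules(sub_panel, mode="display")
    X = feature_matrix(display_panel, sub_subjects, include_covariates=False)
    result = permutation_importance(
        X,
        labels,
        n_iterations=n_iterations,
        n_trees=n_trees,
        n_repeats=n_repeats,
        seed=seed,
    )
    importance_candidates = select_features(result, threshold=importance_threshold)

    # stage 3: intersection, ordered by importance
    in_ratio = set(ratio_candidates)
    intersection = [a for a in importance_candidates if a in in_ratio]

    # stage 4: per-analyte ROC pruning
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    log_values = ratio_panel.log_frame()
    per_auc: dict[str, tuple[float, float, float]] = {}
    for name in intersection:
        r = roc(log_values[name].to_numpy(), labels, auto_orient=True, rng=rng)
        per_auc[name] = (r.auc, r.auc_ci[0], r.auc_ci[1])
    if len(intersection) < panel_size:
        warnings.warn(
            f"candidate intersection has {len(intersection)} analytes "
            f"(< requested panel size {panel_size}); returning as-is"
        )
        final = list(intersection)
    else:
        ranked = sorted(
            intersection,
            key=lambda a: (per_auc[a][0], -(per_auc[a][2] - per_auc[a][1])),
            reverse=True,
        )
        final = sorted(ranked[:panel_size], key=intersection.index)
    return PanelDerivation(
        ratio_candidates=ratio_candidates,
        importance_candidates=importance_candidates,
        intersection=intersection,
        per_analyte_auc=per_auc,
        final_panel=final,
    )


def fit_viper(
    panel: PanelMatrix,
    subjects: list[SubjectRecord],
    analytes: list[str],
    form: str = "logistic_linear_on_logs",
    expression: str | None = None,
    seed: int = 0,
) -> ViperModel:
    """Fit the survival score on discharged-home vs deceased subjects.

    The default form is a logistic model linear in the panel's log
    concentrations, by maximum likelihood; on (quasi-)separation the fit
    falls back to a ridge-stabilized logistic regression with a warning.
    ``custom_expression`` skips fitting and stores the formula verbatim.
    """
    if form == "custom_expression":
        if not expression:
            raise ValueError("custom_expression form requires an expression")
        return ViperModel(
            analytes=list(analytes),
            form=form,
            expression_text=expression,
            training_meta={"fitted": False},
        )
    if form != "logistic_linear_on_logs":
        raise ValueError(f"unknown form {form!r}")

    usable, _ = outcome_mask(subjects)
    sub_subjects = [s for s, keep in zip(subjects, usable) if keep]
    y = np.array([s.outcome == "deceased" for s in sub_subjects])
    if y.all() or not y.any():
        raise ValueError("need both outcome classes to fit")
    Z = _log_panel_values(panel.subset(usable), analytes).to_numpy()

    beta, intercept, se = _fit_logistic(Z, y)
    return ViperModel(
        analytes=list(analytes),
        form=form,
        coefficients={a: float(b) for a, b in zip(analytes, beta)},
        intercept=float(intercept),
        training_meta={
            "n": int(y.size),
            "n_deceased": int(y.sum()),
            "seed": seed,
            "exclusions": "non-home non-deceased dispositions, controls",
        },
        se={a: float(s) for a, s in zip(analytes, se)},
    )


def _fit_logistic(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximum-likelihood logistic fit with ridge fallback on separation."""
    Zc = sm.add_constant(Z, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.astype(float), Zc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if np.all(np.isfinite(params)) and np.max(np.abs(params[1:])) < 50 and fit.mle_retvals.get("converged", True):
            se = np.asarray(fit.bse)[1:]
            return params[1:], float(params[0]), se
    except Exception:  # PerfectSeparation or singular information
        pass
    warnings.warn("separation detected; using ridge-stabilized logistic fit")
    clf = LogisticRegression(C=1.0, max_iter=2000).fit(Z, y)
    return clf.coef_[0], float(clf.intercept_[0]), np.full(Z.shape[1], np.nan)


def viper_score(model: ViperModel, log_values: pd.DataFrame | pd.Series) -> pd.Series:
    """Score subjects; higher = higher predicted death risk.

    ``log_values`` holds natural-log ratio-mode concentrations with the
    model's analytes as columns (a Series scores a single subject).  For the
    logistic form the score is the linear predictor (log-odds).  Custom
    expressions are evaluated with each analyte's *concentration* (pg/mL)
    bound to its sanitized name (non-alphanumerics -> ``_``), with ``log``
    and ``exp`` available.  Subjects with a missing analyte are skipped with
    a log message.
    """
    single = isinstance(log_values, pd.Series)
    frame = log_values.to_frame().T if single else log_values
    missing_cols = [a for a in model.analytes if a not in frame.columns]
    if missing_cols:
        raise KeyError(f"analytes missing from input: {missing_cols}")
    frame = frame[model.analytes]
    complete = frame.notna().all(axis=1)
    if not complete.all():
        logger.info("skipping %d subjects with missing analytes", int((~complete).sum()))
        frame = frame[complete]
    if model.form == "logistic_linear_on_logs":
        eta = model.intercept + frame.to_numpy() @ np.array(
            [model.coefficients[a] for a in model.analytes]
        )
        return pd.Series(eta, index=frame.index, name="viper_score")
    namespace: dict[str, object] = {"log": np.log, "exp": np.exp, "__builtins__": {}}
    for a in model.analytes:
        namespace[_sanitize(a)] = np.exp(frame[a].to_numpy())  # concentration scale
    value = eval(model.expression_text, namespace)  # noqa: S307 - restricted namespace
    value = np.broadcast_to(np.asarray(value, dtype=float), (len(frame),)).copy()
    return pd.Series(value, index=frame.index, name="viper_score")


def evaluate_by_level(
    model: ViperModel,
    panel: PanelMatrix,
    subjects: list[SubjectRecord],
    strata: tuple = ("all", 1, 4),
    method: str = "cv",
    n_splits: int = 5,
    seed: int = 0,
) -> dict[str, RocResult]:
    """ROC of the score per trauma-level stratum.

    ``cv`` (default) refits the model per stratified fold and pools
    out-of-fold scores, so every subject is scored by a model that never saw
    it; ``resubstitution`` scores with the supplied model directly.  Strata
    with a single outcome class are skipped with a warning.
    """
    usable, _ = outcome_mask(subjects)
    sub_subjects = [s for s, keep in zip(subjects, usable) if keep]
    y = np.array([s.outcome == "deceased" for s in sub_subjects])
    frame = _log_panel_values(panel.subset(usable), model.analytes)
    complete = frame.notna().all(axis=1).to_numpy()
    frame, y = frame[complete], y[complete]
    sub_subjects = [s for s, keep in zip(sub_subjects, complete) if keep]

    if method == "resubstitution":
        scores = viper_score(model, frame).to_numpy()
    elif method == "cv":
        if model.form != "logistic_linear_on_logs":
            raise ValueError("cross-validated evaluation requires the fitted form")
        Z = frame.to_numpy()
        scores = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train, test in skf.split(Z, y):
            beta, intercept, _ = _fit_logistic(Z[train], y[train])
            scores[test] = intercept + Z[test] @ beta
    else:
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out: dict[str, RocResult] = {}
    levels = np.array(
        [s.trauma_level if s.trauma_level is not None else -1 for s in sub_subjects]
    )
    for stratum in strata:
        mask = np.ones(len(y), dtype=bool) if stratum == "all" else levels == stratum
        if not y[mask].any() or y[mask].all():
            warnings.warn(f"stratum {stratum!r} has one outcome class; skipped")
            continue
        out[str(stratum)] = roc(scores[mask], y[mask], rng=rng)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def run_pipeline(
    config: dict | str | Path | None = None,
    seed: int | None = None,
    outdir: str | Path = "viper_out",
) -> dict:
    """Execute the full analysis and write a tidy report bundle.

    Stages: load or simulate the cohort -> LOD rules -> per-analyte Tobit
    (trauma vs control) with directional FDR -> below-LOD prevalence ->
    ratio fold-change screen -> permutation importance -> panel derivation
    -> VIPER fit -> per-level ROC evaluation.  A stage failure raises with
    the stage name; outputs written so far are preserved.

    Config keys (YAML or dict): ``inputs: {panel, lods, clinical}`` or
    ``synthetic: {n_trauma, n_control}``; ``analysis: {fdr_alpha,
    n_top_pairs, importance_threshold, panel_size, n_trees, n_iterations,
    cv_folds}``; ``seed``.
    """
    cfg = _load_config(config)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    analysis = cfg.get("analysis", {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(msg: str) -> None:
        line = f"[{time.time() - t0:8.2f}s] {msg}"
        log_lines.append(line)
        logger.info(msg)

    summary: dict = {"seed": seed}
    stage = "inputs"
    try:
        if "inputs" in cfg:
            paths = cfg["inputs"]
            for key in ("panel", "lods", "clinical"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"inputs.{key} missing or not found: {paths.get(key)}"
                    )
            panel, subjects = panel_io.read_panel(
                paths["panel"], paths["lods"], paths["clinical"]
            )
            log(f"loaded panel {panel.shape} from {paths['panel']}")
        else:
            syn = cfg.get("synthetic", {})
            cohort = default_paperlike_config(
                seed=seed,
                n_trauma=int(syn.get("n_trauma", 1000)),
                n_control=int(syn.get("n_control", 50)),
            )
            panel, subjects, truth = generate(cohort)
            truth.to_csv(outdir / "truth.csv", index=False)
            panel_io.write_panel(panel, outdir / "panel.csv")
            panel_io.write_lod_sidecar(panel.analytes, outdir / "lods.csv")
            panel_io.write_clinical(subjects, outdir / "clinical.csv")
            log(f"simulated cohort {panel.shape} (seed {seed})")
        summary["n_subjects"], summary["n_analytes"] = panel.shape

        stage = "tobit"
        processed = apply_lod_rules(panel, mode="analysis")
        fits = fit_panel(processed, subjects, model="univariable_group")
        directional_fdr(fits, alpha=float(analysis.get("fdr_alpha", 0.01)))
        tobit_table = results_frame(fits, model="univariable_group")
        tobit_table.to_csv(outdir / "tobit_trauma_vs_control.csv", index=False)
        sig = tobit_table[tobit_table["significant"]]
        summary["n_significant_up"] = int((sig["direction"] == "positive").sum())
        summary["n_significant_down"] = int((sig["direction"] == "negative").sum())
        log(
            f"tobit: {summary['n_significant_up']} up / "
            f"{summary['n_significant_down']} down at FDR"
        )

        stage = "lod_prevalence"
        prev = lod_prevalence_compare(panel, subjects)
        pd.DataFrame([vars(p) for p in prev]).to_csv(
            outdir / "lod_prevalence.csv", index=False
        )
        summary["n_more_below_in_trauma"] = sum(
            1 for p in prev if p.q_value < 0.05 and p.difference > 0
        )
        log(f"below-LOD prevalence: {summary['n_more_below_in_trauma']} analytes higher in trauma")

        stage = "ratio_screen"
        usable, _ = outcome_mask(subjects)
        ratio_panel = apply_lod_rules(panel.subset(usable), mode="ratio")
        sub_subjects = [s for s, keep in zip(subjects, usable) if keep]
        table = fold_change_matrix(ratio_panel, sub_subjects)
        table.fold.to_csv(outdir / "ratio_fold_matrix.csv")
        table.pairs().to_csv(outdir / "ratio_pairs.csv", index=False)
        log("ratio screen done")

        stage = "derive_panel"
        derivation = derive_panel(
            panel,
            subjects,
            n_top_pairs=int(analysis.get("n_top_pairs", 30)),
            importance_threshold=float(analysis.get("importance_threshold", 10.0)),
            panel_size=int(analysis.get("panel_size", DEFAULT_PANEL_SIZE)),
            n_trees=int(analysis.get("n_trees", 200)),
            n_iterations=int(analysis.get("n_iterations", 10)),
            seed=seed,
        )
        (outdir / "derivation.json").write_text(
            json.dumps(asdict(derivation), indent=2, default=float)
        )
        summary["final_panel"] = derivation.final_panel
        log(f"derived panel: {derivation.final_panel}")

        stage = "fit_viper"
        model = fit_viper(panel, subjects, derivation.final_panel, seed=seed)
        (outdir / "viper_model.json").write_text(model.to_json())
        log("viper fitted")

        stage = "evaluate"
        rocs = evaluate_by_level(
            model,
            panel,
            subjects,
            n_splits=int(analysis.get("cv_folds", 5)),
            seed=seed,
        )
        roc_summary = {
            name: {"auc": r.auc, "ci": list(r.auc_ci), "n_pos": r.n_pos, "n_neg": r.n_neg}
            for name, r in rocs.items()
        }
        (outdir / "viper_roc.json").write_text(json.dumps(roc_summary, indent=2))
        if "all" in rocs:
            rocs["all"].to_frame().to_csv(outdir / "viper_roc_coordinates.csv", index=False)
        summary["viper_auc"] = {k: v["auc"] for k, v in roc_summary.items()}
        log(f"viper AUC by stratum: {summary['viper_auc']}")
    except Exception as exc:
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
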
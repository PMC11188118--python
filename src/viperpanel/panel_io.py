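"""Panel input/output and limit-of-detection (LOD) handling.

Multiplex electrochemiluminescence immunoassays quantify each analyte only
inside an analyte-specific detection window.  Measurements outside that window
are *censored*, not missing: a cell below the lower LOD says "present at some
concentration under ``lower_lod``".  This module reads subject-by-analyte
concentration tables together with a per-analyte LOD sidecar and a clinical
covariate table, derives a censoring status for every cell, and applies the
preprocessing rules the downstream analyses rely on:

* values above the upper LOD are set to ``upper_lod * 1.1`` in every mode;
* values below the lower LOD are
  - flagged left-censored at ``log(lower_lod)`` for regression (``analysis``),
  - set to 0 before within-marker 0-100 normalization (``display``),
  - replaced by ``min(curve_min, lowest detected value)`` for ratio work
    (``ratio``);
* all concentrations are natural-log transformed (so a regression coefficient
  beta maps to a percent change ``(e**beta - 1) * 100``).

Missing cells (empty in the file) are distinct from below-LOD cells and are
excluded from every analysis, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteDef",
    "SubjectRecord",
    "PanelMatrix",
    "ProcessedPanel",
    "PanelSchemaError",
    "BELOW",
    "WITHIN",
    "ABOVE",
    "MISSING",
    "LOD_SENTINEL",
    "read_panel",
    "write_panel",
    "write_lod_sidecar",
    "write_clinical",
    "read_clinical",
    "apply_lod_rules",
    "normalize_within_marker",
    "display_matrix",
]

# Per-cell censoring status codes.
BELOW = "below"
WITHIN = "within"
ABOVE = "above"
MISSING = "missing"

#: Sentinel string some vendor exports use for below-LOD cells.
LOD_SENTINEL = "<LOD"

GROUPS = frozenset({"trauma", "control"})
SEXES = frozenset({"female", "male", "unknown"})
OUTCOMES = frozenset(
    {"discharged_home", "other_discharge", "icu", "or_", "deceased", "unknown"}
)
MECHANISMS = frozenset({"fall", "gsw", "mvc", "stab", "other", "unknown"})
LOCATIONS = frozenset({"head_neck", "torso", "peripheral", "unknown"})
WOUND_TYPES = frozenset({"internal", "penetrating", "bone", "soft_tissue"})
COVID = frozenset({"positive", "negative", "untested"})


class PanelSchemaError(ValueError):
    """Input tables are mutually inconsistent (names, ids, vocabularies)."""


@dataclass(frozen=True)
class AnalyteDef:
    """One analyte's identity and detection window (concentrations in pg/mL)."""

    name: str
    lower_lod: float
    upper_lod: float
    curve_min: float | None = None  # lowest standard-curve point, if known

    def __post_init__(self) -> None:
        if not (0 < self.lower_lod < self.upper_lod):
            raise ValueError(
                f"analyte {self.name!r}: need 0 < lower_lod < upper_lod, "
                f"got ({self.lower_lod}, {self.upper_lod})"
            )
        if self.curve_min is not None and not self.curve_min > 0:
            raise ValueError(f"analyte {self.name!r}: curve_min must be > 0")


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical covariates and discharge outcome for one subject."""

    id: str
    group: str
    age: float
    sex: str = "unknown"
    trauma_level: int | None = None  # 1 (most severe) .. 4 (alert); trauma only
    outcome: str = "unknown"
    mechanism: str = "unknown"
    locations: frozenset[str] = field(default_factory=frozenset)
    wound_type: frozenset[str] = field(default_factory=frozenset)
    covid: str = "untested"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"subject {self.id}: unknown sex {self.sex!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"subject {self.id}: unknown outcome {self.outcome!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"subject {self.id}: unknown mechanism {self.mechanism!r}")
        if not set(self.locations) <= LOCATIONS:
            raise ValueError(f"subject {self.id}: bad locations {self.locations}")
        if not set(self.wound_type) <= WOUND_TYPES:
            raise ValueError(f"subject {self.id}: bad wound_type {self.wound_type}")
        if self.covid not in COVID:
            raise ValueError(f"subject {self.id}: bad covid status {self.covid!r}")
        if self.age < 0:
            raise ValueError(f"subject {self.id}: negative age")
        if self.trauma_level is not None:
            if self.group != "trauma":
                raise ValueError(f"subject {self.id}: trauma_level set on control")
            if self.trauma_level not in (1, 2, 3, 4):
                raise ValueError(f"subject {self.id}: trauma_level must be 1-4")


@dataclass
class PanelMatrix:
    """Subject x analyte raw concentrations with per-cell censoring status.

    ``raw`` holds concentrations in pg/mL (NaN where the file cell was empty
    or a below-LOD sentinel with no numeric value).  ``status`` holds one of
    ``below / within / above / missing`` per cell, derived by comparing raw
    values against each analyte's LODs.
    """

    subject_ids: list[str]
    analytes: list[AnalyteDef]
    raw: np.ndarray  # (n_subjects, n_analytes) float64
    status: np.ndarray  # (n_subjects, n_analytes) object of status codes

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        n, k = len(self.subject_ids), len(self.analytes)
        if self.raw.shape != (n, k) or self.status.shape != (n, k):
            raise ValueError("raw/status shape does not match ids/analytes")
        if len(set(self.subject_ids)) != n:
            raise PanelSchemaError("duplicate subject id in panel")

    @property
    def analyte_names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.subject_ids, columns=self.analyte_names)

    def status_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.status, index=self.subject_ids, columns=self.analyte_names
        )

    def subset(self, subject_mask: np.ndarray) -> "PanelMatrix":
        """Row-subset by a boolean mask over subjects."""
        subject_mask = np.asarray(subject_mask, dtype=bool)
        ids = [s for s, keep in zip(self.subject_ids, subject_mask) if keep]
        return PanelMatrix(ids, self.analytes, self.raw[subject_mask], self.status[subject_mask])

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        analytes: list[AnalyteDef],
        below_sentinel: np.ndarray | None = None,
    ) -> "PanelMatrix":
        """Build a matrix from raw concentrations, deriving statuses from LODs.

        ``below_sentinel`` marks cells that carried the textual below-LOD
        sentinel (no numeric value); they become status ``below`` with NaN raw.
        """
        names = [a.name for a in analytes]
        if list(raw.columns) != names:
            raise PanelSchemaError("raw columns do not match analyte definitions")
        values = raw.to_numpy(dtype=float)
        status = np.empty(values.shape, dtype=object)
        status[:] = MISSING
        for j, a in enumerate(analytes):
            col = values[:, j]
            ok = np.isfinite(col)
            status[ok & (col < a.lower_lod), j] = BELOW
            status[ok & (col > a.upper_lod), j] = ABOVE
            status[ok & (col >= a.lower_lod) & (col <= a.upper_lod), j] = WITHIN
        if below_sentinel is not None:
            status[np.asarray(below_sentinel, dtype=bool)] = BELOW
        return cls(list(raw.index), analytes, values, status)


@dataclass
class ProcessedPanel:
    """LOD-rule-applied concentrations, natural-log transformed.

    ``conc`` is the concentration-scale value after the mode's substitution
    rules; ``log_conc`` its natural log (``display`` mode instead stores the
    display value: log concentration for detected cells, 0 for below-LOD
    cells).  ``censor_left`` flags cells that are left-censored for regression
    (only set in ``analysis`` mode); for those cells ``log_conc`` holds the
    censoring threshold ``log(lower_lod)``.
    """

    subject_ids: list[str]
    analytes: list[AnalyteDef]
    mode: str
    conc: np.ndarray
    log_conc: np.ndarray
    censor_left: np.ndarray  # boolean
    censor_threshold: np.ndarray  # (n_analytes,) log(lower_lod)

    @property
    def analyte_names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log_conc, index=self.subject_ids, columns=self.analyte_names
        )

    def conc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.conc, index=self.subject_ids, columns=self.analyte_names
        )

    def subset(self, subject_mask: np.ndarray) -> "ProcessedPanel":
        subject_mask = np.asarray(subject_mask, dtype=bool)
        ids = [s for s, keep in zip(self.subject_ids, subject_mask) if keep]
        return replace(
            self,
            subject_ids=ids,
            conc=self.conc[subject_mask],
            log_conc=self.log_conc[subject_mask],
            censor_left=self.censor_left[subject_mask],
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_lod_sidecar(lod_path: str | Path) -> dict[str, AnalyteDef]:
    lods = pd.read_csv(lod_path)
    required = {"analyte", "lower_lod", "upper_lod"}
    if not required <= set(lods.columns):
        raise PanelSchemaError(f"LOD sidecar must have columns {sorted(required)}")
    defs: dict[str, AnalyteDef] = {}
    for _, row in lods.iterrows():
        curve_min = row.get("curve_min", np.nan)
        curve_min = None if pd.isna(curve_min) else float(curve_min)
        defs[str(row["analyte"])] = AnalyteDef(
            name=str(row["analyte"]),
            lower_lod=float(row["lower_lod"]),
            upper_lod=float(row["upper_lod"]),
            curve_min=curve_min,
        )
    return defs


def read_clinical(clinical_path: str | Path) -> list[SubjectRecord]:
    """Read the clinical covariate table (one row per subject)."""
    df = pd.read_csv(clinical_path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise PanelSchemaError("clinical table must have an 'id' column")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise PanelSchemaError(f"duplicate subject id in clinical table: {dup!r}")
    records = []
    for _, row in df.iterrows():
        level = row.get("trauma_level", "")
        records.append(
            SubjectRecord(
                id=row["id"],
                group=row["group"],
                age=float(row["age"]),
                sex=row.get("sex", "unknown") or "unknown",
                trauma_level=int(float(level)) if level not in ("", "none") else None,
                outcome=row.get("outcome", "unknown") or "unknown",
                mechanism=row.get("mechanism", "unknown") or "unknown",
                locations=frozenset(x for x in row.get("locations", "").split(";") if x),
                wound_type=frozenset(x for x in row.get("wound_type", "").split(";") if x),
                covid=row.get("covid", "untested") or "untested",
            )
        )
    return records


def read_panel(
    panel_path: str | Path,
    lod_path: str | Path,
    clinical_path: str | Path,
) -> tuple[PanelMatrix, list[SubjectRecord]]:
    """Read a concentration panel, its LOD sidecar, and the clinical table.

    The panel is a CSV with subjects as rows (first column = subject id) and
    analytes as columns (pg/mL).  Empty cells become ``missing``; cells equal
    to the ``<LOD`` sentinel become ``below`` with NaN raw value; numeric
    cells get their status by comparison against the analyte's LODs.
    """
    table = pd.read_csv(panel_path, index_col=0, dtype=str, keep_default_na=False)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise PanelSchemaError(f"duplicate subject id in panel: {dup!r}")
    defs = _read_lod_sidecar(lod_path)
    analytes = []
    for name in table.columns:
        if name not in defs:
            raise PanelSchemaError(f"analyte {name!r} missing from LOD sidecar")
        analytes.append(defs[name])

    cells = table.to_numpy(dtype=object)
    sentinel = np.zeros(cells.shape, dtype=bool)
    raw = np.full(cells.shape, np.nan)
    for idx, cell in np.ndenumerate(cells):
        text = str(cell).strip()
        if text == "":
            continue
        if text.upper() == LOD_SENTINEL.upper():
            sentinel[idx] = True
            continue
        raw[idx] = float(text)
    raw_df = pd.DataFrame(raw, index=list(table.index), columns=list(table.columns))
    panel = PanelMatrix.from_raw(raw_df, analytes, below_sentinel=sentinel)

    subjects = read_clinical(clinical_path)
    by_id = {s.id: s for s in subjects}
    missing_ids = [s for s in panel.subject_ids if s not in by_id]
    if missing_ids:
        raise PanelSchemaError(f"subjects absent from clinical table: {missing_ids[:5]}")
    # return clinical records in panel row order
    return panel, [by_id[s] for s in panel.subject_ids]


def write_panel(panel: PanelMatrix, panel_path: str | Path) -> None:
    """Write raw concentrations; below-LOD cells without a stored value get
    the ``<LOD`` sentinel so a read round-trips statuses exactly."""
    out = panel.raw_frame().astype(object)
    for (i, j), st in np.ndenumerate(panel.status):
        if st == BELOW and not np.isfinite(panel.raw[i, j]):
            out.iat[i, j] = LOD_SENTINEL
        elif st == MISSING:
            out.iat[i, j] = ""
        else:
            out.iat[i, j] = repr(float(panel.raw[i, j]))
    out.index.name = "id"
    out.to_csv(panel_path)


def write_lod_sidecar(analytes: list[AnalyteDef], lod_path: str | Path) -> None:
    pd.DataFrame(
        {
            "analyte": [a.name for a in analytes],
            "lower_lod": [repr(a.lower_lod) for a in analytes],
            "upper_lod": [repr(a.upper_lod) for a in analytes],
            "curve_min": ["" if a.curve_min is None else repr(a.curve_min) for a in analytes],
        }
    ).to_csv(lod_path, index=False)


def write_clinical(subjects: list[SubjectRecord], clinical_path: str | Path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "trauma_level": "" if s.trauma_level is None else s.trauma_level,
                "outcome": s.outcome,
                "mechanism": s.mechanism,
                "locations": ";".join(sorted(s.locations)),
                "wound_type": ";".join(sorted(s.wound_type)),
                "covid": s.covid,
            }
        )
    pd.DataFrame(rows).to_csv(clinical_path, index=False)


# ---------------------------------------------------------------------------
# LOD rules and normalization
# ---------------------------------------------------------------------------


def apply_lod_rules(panel: PanelMatrix, mode: str = "analysis") -> ProcessedPanel:
    """Apply mode-specific LOD substitution rules and log-transform.

    ``analysis``: above-LOD cells -> upper_lod*1.1, below-LOD cells flagged
    left-censored at log(lower_lod).  ``display``: below-LOD cells -> 0
    (applied before 0-100 normalization).  ``ratio``: below-LOD cells ->
    min(curve_min, lowest detected value of that analyte).
    """
    if mode not in ("analysis", "display", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    n, k = panel.shape
    conc = panel.raw.copy()
    log_conc = np.full((n, k), np.nan)
    censor = np.zeros((n, k), dtype=bool)
    thresholds = np.array([np.log(a.lower_lod) for a in panel.analytes])

    for j, a in enumerate(panel.analytes):
        st = panel.status[:, j]
        above = st == ABOVE
        below = st == BELOW
        within = st == WITHIN
        conc[above, j] = a.upper_lod * 1.1  # every mode
        if mode == "analysis":
            conc[below, j] = a.lower_lod  # placeholder at the threshold
            censor[below, j] = True
        elif mode == "display":
            conc[below, j] = 0.0
        else:  # ratio
            detected = conc[within, j]
            candidates = []
            if a.curve_min is not None:
                candidates.append(a.curve_min)
            if detected.size:
                candidates.append(float(np.min(detected)))
            if below.any():
                if not candidates:
                    raise ValueError(
                        f"analyte {a.name!r}: no substitution value for below-LOD "
                        "cells (no curve_min and no detected values)"
                    )
                conc[below, j] = min(candidates)
        observed = within | above | (below if mode == "ratio" else np.zeros(n, bool))
        log_conc[observed, j] = np.log(conc[observed, j])
        if mode == "analysis":
            log_conc[below, j] = thresholds[j]
        elif mode == "display":
            # display value: log concentration for detected, 0 for below-LOD
            log_conc[below, j] = 0.0
    return ProcessedPanel(
        subject_ids=list(panel.subject_ids),
        analytes=list(panel.analytes),
        mode=mode,
        conc=conc,
        log_conc=log_conc,
        censor_left=censor,
        censor_threshold=thresholds,
    )


def normalize_within_marker(values: np.ndarray) -> np.ndarray:
    """Affine map of one analyte's values onto [0, 100] (min->0, max->100).

    NaNs are passed through.  A constant vector maps to all zeros with a
    warning (there is no scale to stretch).
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        return out
    lo, hi = np.min(values[finite]), np.max(values[finite])
    if hi == lo:
        warnings.warn("constant vector in normalize_within_marker; returning zeros")
        out[finite] = 0.0
        return out
    out[finite] = (values[finite] - lo) / (hi - lo) * 100.0
    return out


def display_matrix(panel: PanelMatrix) -> pd.DataFrame:
    """Heatmap-ready matrix: display-mode values normalized 0-100 per analyte.

    Below-LOD zeros are applied before normalization, so heavily censored
    analytes pin at 0 exactly as in the published heatmap convention.
    """
    processed = apply_lod_rules(panel, mode="display")
    values = processed.log_conc.copy()
    for j in range(values.shape[1]):
        values[:, j] = normalize_within_marker(values[:, j])
    return pd.DataFrame(values, index=panel.subject_ids, columns=panel.analyte_names)
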
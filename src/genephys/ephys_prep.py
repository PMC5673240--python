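"""Ephys measurement preprocessing and cross-study condition normalization.

Literature-curated electrophysiology is heterogeneous: articles differ in
species, electrode type, junction-potential handling, animal age and
recording temperature.  This module filters the curated records, fits one
penalized additive regression per property,

    EphysProp ~ NeuronType + Species + JxnPotential + ElectrodeType
                + bs(log10(AnimalAge), df=5) + bs(RecTemp, df=5)

(elastic net, mixing weight 0.99, 100-value penalty path, penalty chosen by
article-grouped cross-validation), and uses it to move every measurement to
a common reference condition.  Cell-type terms participate in the fit but
are never adjusted away -- they are the biological signal under study.

Also provides cell-type summarization (article means, then the median
across articles) and the derived single-cell features: spike-frequency
adaptation (first / mean inter-spike interval), capacitance (tau / R_in),
and maximal firing rate from the sweep with the most spikes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.linear_model import ElasticNetCV

from .datamodel_io import (
    EphysMeasurement,
    LOG10_PROPERTIES,
    PROPERTY_CODES,
    RunConfig,
    VOLTAGE_PROPERTIES,
    check_property,
    ephys_records_to_frame,
)

logger = logging.getLogger("genephys.ephys_prep")

__all__ = [
    "ConditionModel",
    "preprocess_measurements",
    "fit_condition_model",
    "adjust_measurements",
    "summarize_ephys_by_cell_type",
    "compute_sfa",
    "derive_capacitance",
    "select_max_rate_sweep",
]

SPLINE_DF = 5
SPLINE_DEGREE = 3
ALLOWED_SPECIES = ("mouse", "rat", "guinea_pig")

_CATEGORICAL_TERMS = ("cell_type_label", "species", "jxn_status", "electrode")


# ---------------------------------------------------------------------------
# Filtering / preprocessing
# ---------------------------------------------------------------------------

def _point_age(r: EphysMeasurement) -> float | None:
    """Collapse an age range to its geometric mean; None when unreported."""
    if r.age_lo_days is None:
        return None
    if r.age_hi_days is None or r.age_hi_days == r.age_lo_days:
        return float(r.age_lo_days)
    return float(np.sqrt(r.age_lo_days * r.age_hi_days))


def preprocess_measurements(
    records: Sequence[EphysMeasurement], cfg: RunConfig
) -> list[EphysMeasurement]:
    """Filter and standardize curated ephys records.

    Keeps acute-slice recordings from mouse/rat/guinea pig with animal age
    > 2 days; collapses age ranges to the geometric mean; median-imputes
    missing age and temperature from the retained records; drops
    (cell type, property) pairs listed in ``cfg.exclusions``; and reverts
    explicit liquid-junction-potential corrections on absolute-voltage
    properties (Vrest, APthr), marking those records post_corrected.
    """
    n0 = len(records)
    kept: list[EphysMeasurement] = []
    removed = {"preparation": 0, "species": 0, "age": 0, "exclusion": 0}
    excl = set(cfg.exclusions)
    for r in records:
        if r.preparation != "acute_slice":
            removed["preparation"] += 1
            continue
        if r.species not in ALLOWED_SPECIES:
            removed["species"] += 1
            continue
        age = _point_age(r)
        if age is not None and age <= 2.0:
            removed["age"] += 1
            continue
        if (r.cell_type_label, r.property) in excl:
            removed["exclusion"] += 1
            continue
        kept.append(dataclasses.replace(r, age_lo_days=age, age_hi_days=age))

    ages = [r.age_lo_days for r in kept if r.age_lo_days is not None]
    temps = [r.rec_temp_C for r in kept if r.rec_temp_C is not None]
    median_age = float(np.median(ages)) if ages else None
    median_temp = float(np.median(temps)) if temps else None

    out: list[EphysMeasurement] = []
    for r in kept:
        changes: dict[str, object] = {}
        if r.age_lo_days is None and median_age is not None:
            changes["age_lo_days"] = median_age
            changes["age_hi_days"] = median_age
        if r.rec_temp_C is None and median_temp is not None:
            changes["rec_temp_C"] = median_temp
        if (
            r.jxn_status == "corrected"
            and r.jxn_offset_mV is not None
            and r.property in VOLTAGE_PROPERTIES
        ):
            changes["value"] = r.value + r.jxn_offset_mV
            changes["jxn_status"] = "post_corrected"
        out.append(dataclasses.replace(r, **changes) if changes else r)

    logger.info(
        "preprocess_measurements: kept %d of %d records (removed %s)",
        len(out), n0, removed,
    )
    return out


# ---------------------------------------------------------------------------
# Condition model
# ---------------------------------------------------------------------------

@dataclass
class ConditionModel:
    """Serializable fitted condition-normalization model for one property.

    ``coefficients`` maps design-column names (e.g. ``"electrode=sharp"``,
    ``"bs_age_3"``) to coefficients on the modeling scale;
    ``categorical_levels`` records, per categorical term, the observed
    levels in fit order (the first is the dummy-coding baseline);
    ``basis_definitions`` carries both splines' full knot vectors so the
    design columns are exactly reproducible; ``reference_conditions`` is
    the covariate point every measurement is adjusted to.
    """

    property: str
    transform: str
    coefficients: dict[str, float]
    intercept: float
    categorical_levels: dict[str, list[str]]
    basis_definitions: dict[str, dict]
    reference_conditions: dict[str, object]
    fit_diagnostics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text: str) -> "ConditionModel":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "ConditionModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _spline_basis(x: np.ndarray, basis_def: dict) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the stored df=5 cubic B-spline basis, clamping out-of-range
    inputs to the boundary knots.  Returns (n x 5 columns, clamped mask)."""
    knots = np.asarray(basis_def["knots"], dtype=float)
    lo, hi = basis_def["boundary"]
    clamped = (x < lo) | (x > hi)
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, knots, SPLINE_DEGREE).toarray()
    # drop the first column, as in R's bs(): df columns without an intercept
    return design[:, 1:], clamped


def _make_basis_def(x: np.ndarray) -> dict | None:
    """Knot vector for a df=5 cubic basis: internal knots at terciles of the
    observed values, boundary knots at the observed range.  None when the
    covariate is constant (no spline possible)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return None
    # inverted-CDF quantiles are invariant to duplicating every record
    internal = np.quantile(x, [1 / 3, 2 / 3], method="inverted_cdf")
    internal = internal[(internal > lo) & (internal < hi)]
    knots = np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), internal, [hi] * (SPLINE_DEGREE + 1)]
    )
    return {"knots": knots.tolist(), "boundary": [lo, hi]}


def _records_frame(records: Sequence[EphysMeasurement], prop: str) -> pd.DataFrame:
    df = ephys_records_to_frame(records)
    df = df[df["property"] == prop].reset_index(drop=True)
    df["age_days"] = df["age_lo_days"]
    return df


def _design_matrix(
    df: pd.DataFrame,
    categorical_levels: dict[str, list[str]],
    basis_definitions: dict[str, dict],
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Build the additive design from a preprocessed record frame.

    Returns (matrix, column names, unseen-level mask, clamped-spline mask).
    Rows with a categorical level unseen at fit time are flagged so callers
    can leave them unadjusted.
    """
    n = len(df)
    cols: list[np.ndarray] = []
    names: list[str] = []
    unseen = np.zeros(n, dtype=bool)
    for term, levels in categorical_levels.items():
        observed = df[term].astype(str).to_numpy()
        unseen |= ~np.isin(observed, levels)
        for level in levels[1:]:
            cols.append((observed == level).astype(float))
            names.append(f"{term}={level}")
    clamped = np.zeros(n, dtype=bool)
    for name, key, values in [
        ("bs_age", "age", np.log10(df["age_days"].to_numpy(dtype=float))),
        ("bs_temp", "temp", df["rec_temp_C"].to_numpy(dtype=float)),
    ]:
        bdef = basis_definitions.get(key)
        if bdef is None:
            continue
        basis, cl = _spline_basis(values, bdef)
        clamped |= cl
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"{name}_{j + 1}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names, unseen, clamped


def _grouped_cv_splits(groups: np.ndarray, n_splits: int) -> list:
    """Article-grouped K-fold with deterministic round-robin assignment in
    order of first appearance, so duplicating every record (which scales all
    group sizes uniformly) leaves the partition of articles unchanged."""
    order: dict = {}
    for g in groups:
        if g not in order:
            order[g] = len(order) % n_splits
    fold_of = np.array([order[g] for g in groups])
    idx = np.arange(len(groups))
    return [
        (idx[fold_of != k], idx[fold_of == k])
        for k in range(n_splits)
        if np.any(fold_of == k)
    ]


def fit_condition_model(
    records: Sequence[EphysMeasurement],
    prop: str,
    cfg: RunConfig,
    reference_conditions: dict | None = None,
) -> ConditionModel:
    """Fit the penalized additive condition model for one property.

    Values of the log10 set (Rin, Tau, APhw, Cm, Rheo, FRmax) are log10
    transformed first (non-positive values are a hard error).  Categorical
    terms with a single observed level are dropped with a warning.  The
    penalty is chosen by cross-validation over ``cfg.enet_nlambda`` values
    at mixing weight ``cfg.enet_alpha``, with folds grouped by article so a
    study never straddles a fold boundary.

    ``reference_conditions`` defaults to the most frequent level of each
    categorical term and the median log10(age) / temperature.
    """
    check_property(prop)
    df = _records_frame(records, prop)
    if df["cell_type_label"].nunique() < 2:
        raise ValueError(f"{prop}: need >= 2 distinct cell types to fit")
    if len(df) < 10:
        raise ValueError(f"{prop}: need >= 10 records to fit, have {len(df)}")

    transform = "log10" if prop in LOG10_PROPERTIES else "identity"
    y_raw = df["value"].to_numpy(dtype=float)
    if transform == "log10":
        bad = np.nonzero(y_raw <= 0)[0]
        if bad.size:
            r = df.iloc[bad[0]]
            raise ValueError(
                f"{prop}: non-positive value {r['value']} in article "
                f"{r['article_id']} ({r['cell_type_label']}) cannot be log10 transformed"
            )
        y = np.log10(y_raw)
    else:
        y = y_raw

    categorical_levels: dict[str, list[str]] = {}
    for term in _CATEGORICAL_TERMS:
        levels = sorted(df[term].astype(str).unique().tolist())
        if term != "cell_type_label" and len(levels) < 2:
            logger.warning(
                "fit_condition_model[%s]: term %s has a single level (%s); dropped",
                prop, term, levels,
            )
            continue
        categorical_levels[term] = levels

    basis_definitions: dict[str, dict] = {}
    age_def = _make_basis_def(np.log10(df["age_days"].to_numpy(dtype=float)))
    if age_def is not None:
        basis_definitions["age"] = age_def
    else:
        logger.warning("fit_condition_model[%s]: constant age; age spline dropped", prop)
    temp_def = _make_basis_def(df["rec_temp_C"].to_numpy(dtype=float))
    if temp_def is not None:
        basis_definitions["temp"] = temp_def
    else:
        logger.warning("fit_condition_model[%s]: constant temperature; temp spline dropped", prop)

    covariate_levels = {t: lv for t, lv in categorical_levels.items() if t != "cell_type_label"}
    X, names, _, _ = _design_matrix(df, covariate_levels, basis_definitions)

    # Cell-type terms are unpenalized fixed effects: partial them out by
    # within-type centering of the target and every condition column, then
    # fit the penalized model on the within-type variation only.  This
    # keeps biological between-type differences out of the condition
    # coefficients (cell types are confounded with e.g. age).
    type_codes = df["cell_type_label"].astype(str)
    y_c = y - pd.Series(y).groupby(type_codes.to_numpy()).transform("mean").to_numpy()
    Xdf = pd.DataFrame(X)
    X_c = (Xdf - Xdf.groupby(type_codes.to_numpy()).transform("mean")).to_numpy()

    # standardize columns (glmnet-style) so the penalty treats terms evenly
    sd = X_c.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = X_c / sd_safe

    if X.shape[1] == 0 or not np.any(sd > 0):
        # no usable condition variation: the model reduces to cell-type means
        logger.warning(
            "fit_condition_model[%s]: no condition variation; model reduces "
            "to cell-type means", prop,
        )
        coef_orig = np.zeros(X.shape[1])
        fit_diag = {"chosen_alpha": float("nan"), "l1_ratio": float(cfg.enet_alpha),
                    "n_records": float(len(df)), "cv_mse": float("nan")}
    else:
        groups = df["article_id"].to_numpy()
        n_groups = len(np.unique(groups))
        n_splits = min(10, n_groups)
        if n_splits < 2:
            raise ValueError(f"{prop}: need records from >= 2 articles for grouped CV")
        splits = _grouped_cv_splits(groups, n_splits)
        enet = ElasticNetCV(
            l1_ratio=cfg.enet_alpha,
            alphas=cfg.enet_nlambda,
            cv=splits,
            fit_intercept=True,
            max_iter=100000,
            tol=1e-6,
        )
        enet.fit(Xs, y_c)
        coef_orig = enet.coef_ / sd_safe
        fit_diag = {"chosen_alpha": float(enet.alpha_), "l1_ratio": float(cfg.enet_alpha),
                    "n_records": float(len(df)),
                    "cv_mse": float(np.min(enet.mse_path_.mean(axis=-1)))}
    coefficients = {name: float(c) for name, c in zip(names, coef_orig)}

    # explicit cell-type effects (and intercept) from the residual type means
    resid = y - X @ coef_orig
    type_means = pd.Series(resid).groupby(type_codes.to_numpy()).mean()
    type_levels = categorical_levels["cell_type_label"]
    for level in type_levels[1:]:
        coefficients[f"cell_type_label={level}"] = float(
            type_means[level] - type_means[type_levels[0]]
        )
    intercept = float(type_means[type_levels[0]])

    if reference_conditions is None:
        reference_conditions = {}
        for term, levels in categorical_levels.items():
            if term == "cell_type_label":
                continue
            reference_conditions[term] = str(df[term].mode().iloc[0])
        log_age = np.log10(df["age_days"].to_numpy(dtype=float))
        reference_conditions["log10_age"] = float(np.median(log_age))
        # age is part of cell-type identity (developmental stages are
        # distinct types), so each type is adjusted to its own median age
        reference_conditions["log10_age_by_type"] = {
            str(t): float(np.median(g))
            for t, g in pd.Series(log_age).groupby(df["cell_type_label"].to_numpy())
        }
        reference_conditions["rec_temp_C"] = float(np.median(df["rec_temp_C"]))

    return ConditionModel(
        property=prop,
        transform=transform,
        coefficients=coefficients,
        intercept=intercept,
        categorical_levels=categorical_levels,
        basis_definitions=basis_definitions,
        reference_conditions=dict(reference_conditions),
        fit_diagnostics=fit_diag,
    )


def _condition_prediction(model: ConditionModel, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted condition contribution (excluding cell-type terms and the
    intercept, which cancel in adjustment deltas) for each record row."""
    cat = {t: lv for t, lv in model.categorical_levels.items() if t != "cell_type_label"}
    X, names, unseen, clamped = _design_matrix(df, cat, model.basis_definitions)
    beta = np.array([model.coefficients.get(n, 0.0) for n in names])
    return X @ beta, unseen, clamped


def adjust_measurements(
    model: ConditionModel, records: Sequence[EphysMeasurement]
) -> list[EphysMeasurement]:
    """Move each measurement of the model's property to reference conditions.

    On the modeling scale: adjusted = observed - (predicted at observed
    covariates - predicted at reference covariates); cell-type terms do not
    enter the delta.  Records carrying a categorical level unseen at fit
    time are returned unadjusted and logged.  Records of other properties
    pass through untouched.
    """
    mine = [r for r in records if r.property == model.property]
    others = [r for r in records if r.property != model.property]
    if not mine:
        return list(records)
    df = _records_frame(mine, model.property)

    ref = model.reference_conditions
    ref_df = df.copy()
    for term in model.categorical_levels:
        if term == "cell_type_label":
            continue
        ref_df[term] = ref[term]
    if "age" in model.basis_definitions:
        by_type = ref.get("log10_age_by_type", {})
        fallback = float(ref["log10_age"])
        ref_df["age_days"] = [
            10.0 ** float(by_type.get(str(t), fallback))
            for t in df["cell_type_label"]
        ]
    if "temp" in model.basis_definitions:
        ref_df["rec_temp_C"] = float(ref["rec_temp_C"])

    pred_obs, unseen, clamped = _condition_prediction(model, df)
    pred_ref, _, _ = _condition_prediction(model, ref_df)
    delta = pred_obs - pred_ref

    if clamped.any():
        logger.info(
            "adjust_measurements[%s]: %d records beyond spline boundary knots "
            "(clamped)", model.property, int(clamped.sum()),
        )
    adjusted: list[EphysMeasurement] = []
    n_unseen = 0
    for i, r in enumerate(mine):
        if unseen[i]:
            n_unseen += 1
            adjusted.append(r)
            continue
        val = np.log10(r.value) if model.transform == "log10" else r.value
        val = val - delta[i]
        new = 10.0 ** val if model.transform == "log10" else val
        adjusted.append(dataclasses.replace(r, value=float(new)))
    if n_unseen:
        logger.warning(
            "adjust_measurements[%s]: %d records left unadjusted "
            "(unseen categorical level)", model.property, n_unseen,
        )
    return adjusted + others


# ---------------------------------------------------------------------------
# Summarization and derived features
# ---------------------------------------------------------------------------

def summarize_ephys_by_cell_type(records: Sequence[EphysMeasurement]) -> pd.DataFrame:
    """Cell-type x property matrix: mean within article, then the median of
    the article means across articles; NaN where a property was never
    measured for a type.  Article counts are logged.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = ephys_records_to_frame(records)
    article_means = (
        df.groupby(["cell_type_label", "property", "article_id"])["value"]
        .mean()
        .reset_index()
    )
    medians = (
        article_means.groupby(["cell_type_label", "property"])["value"].median().unstack()
    )
    counts = (
        article_means.groupby(["cell_type_label", "property"])["article_id"]
        .nunique()
        .unstack()
    )
    props = [p for p in PROPERTY_CODES if p in medians.columns]
    medians = medians[props]
    medians.index.name = "cell_type"
    logger.info(
        "summarize_ephys_by_cell_type: %d cell types x %d properties; "
        "median articles per cell=%s",
        medians.shape[0], medians.shape[1],
        float(np.nanmedian(counts.to_numpy(dtype=float))),
    )
    return medians


def compute_sfa(isis: Sequence[float]) -> float:
    """Spike-frequency adaptation: first inter-spike interval divided by the
    mean interval.  Adapting trains (lengthening ISIs) give values below 1,
    approaching 0 for strong adaptation."""
    arr = np.asarray(isis, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one inter-spike interval")
    if np.any(arr <= 0):
        raise ValueError("inter-spike intervals must be positive")
    return float(arr[0] / arr.mean())


def derive_capacitance(tau_ms: float, rin_Mohm: float) -> float:
    """Membrane capacitance in pF from the time constant (ms) and input
    resistance (MOhm): C_m = tau / R_in (ms/MOhm = nF, reported as pF)."""
    if tau_ms <= 0 or rin_Mohm <= 0:
        raise ValueError("tau and R_in must be positive")
    return float(tau_ms / rin_Mohm * 1000.0)


def select_max_rate_sweep(
    spike_counts_per_sweep: Sequence[int], sweep_duration_s: float
) -> tuple[int, float]:
    """The (1-based) sweep with the most spikes and its firing rate in Hz.

    Ties keep the first sweep (logged).  If no sweep spiked, FRmax is 0 and
    a flag is logged.
    """
    counts = np.asarray(spike_counts_per_sweep)
    if counts.size == 0:
        raise ValueError("need at least one sweep")
    if sweep_duration_s <= 0:
        raise ValueError("sweep duration must be positive")
    idx = int(np.argmax(counts))
    if np.count_nonzero(counts == counts[idx]) > 1:
        logger.info("select_max_rate_sweep: tie at %d spikes; keeping sweep %d", counts[idx], idx + 1)
    if counts[idx] == 0:
        logger.warning("select_max_rate_sweep: no spikes in any sweep; FRmax = 0")
        return idx + 1, 0.0
    return idx + 1, float(counts[idx] / sweep_duration_s)
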
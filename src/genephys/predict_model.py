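"""Sparse multivariate models predicting ephys properties from expression.

Each property is modelled from z-scored gene expression with a two-stage
elastic net (mixing weight 0.99, 100-value penalty path, penalty chosen by
nested cross-validation): stage 1 selects the genes with nonzero
coefficients, stage 2 refits the same penalized procedure on the selected
genes.  Evaluation is leave-one-cell-type-out cross-validation with both
stages and all scaling statistics recomputed inside every fold; the pooled
held-out predictions give R2 = 1 - SSE/SST (the unity-line definition,
possibly negative).  A shuffled-label null and a stratified bootstrap over
the pre-summarization samples/articles quantify chance performance and
sampling variability, and a trained model can be transferred to an
independently normalized validation dataset on a shared standardized
scale.
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
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, LeaveOneOut

from .datamodel_io import (
    EphysMeasurement,
    ExpressionMatrix,
    LOG10_PROPERTIES,
    RunConfig,
    check_property,
    substream,
    to_model_scale,
)
from .expression_prep import filter_genes, summarize_expression_by_cell_type
from .ephys_prep import preprocess_measurements, summarize_ephys_by_cell_type

logger = logging.getLogger("genephys.predict_model")

__all__ = [
    "SparseEphysModel",
    "ModelEvaluation",
    "fit_two_stage",
    "evaluate_loocv",
    "shuffled_label_null",
    "bootstrap_performance",
    "transfer_predict",
]


@dataclass
class SparseEphysModel:
    """A fitted sparse expression -> ephys model for one property.

    ``gene_scaling`` holds the training (mean, sd) of every training gene
    (needed to z-score new data); ``coefficients`` covers exactly
    ``selected_genes``.  ``y_scaling`` is (mean, sd) of the transformed
    training target when the model was fit on a standardized target (the
    transfer setting), else None.
    """

    property: str | None
    transform: str
    gene_scaling: pd.DataFrame  # index: gene; columns: mean, sd
    selected_genes: list[str]
    coefficients: dict[str, float]
    intercept: float
    y_scaling: tuple[float, float] | None = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.coefficients) - set(self.selected_genes)
        if extra:
            raise ValueError(f"coefficients for unselected genes: {sorted(extra)}")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict on the model's target scale from raw expression rows,
        applying the stored per-gene training scaling."""
        missing = [g for g in self.selected_genes if g not in X.columns]
        if missing:
            raise ValueError(f"model genes absent from input: {missing}")
        if not self.selected_genes:
            return np.full(len(X), self.intercept)
        sub = X[self.selected_genes].to_numpy(dtype=float)
        sc = self.gene_scaling.loc[self.selected_genes]
        z = (sub - sc["mean"].to_numpy()) / sc["sd"].to_numpy()
        beta = np.array([self.coefficients[g] for g in self.selected_genes])
        return z @ beta + self.intercept

    def to_json(self, path=None) -> str:
        data = {
            "property": self.property,
            "transform": self.transform,
            "gene_scaling": {
                g: [float(m), float(s)]
                for g, (m, s) in self.gene_scaling[["mean", "sd"]].iterrows()
            },
            "selected_genes": list(self.selected_genes),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "y_scaling": list(self.y_scaling) if self.y_scaling else None,
            "fit_meta": self.fit_meta,
        }
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text: str) -> "SparseEphysModel":
        data = json.loads(text)
        scaling = pd.DataFrame.from_dict(
            data["gene_scaling"], orient="index", columns=["mean", "sd"]
        )
        return cls(
            property=data["property"],
            transform=data["transform"],
            gene_scaling=scaling,
            selected_genes=data["selected_genes"],
            coefficients=data["coefficients"],
            intercept=data["intercept"],
            y_scaling=tuple(data["y_scaling"]) if data["y_scaling"] else None,
            fit_meta=data["fit_meta"],
        )


@dataclass
class ModelEvaluation:
    """Evaluation results for one property's model."""

    property: str | None
    r2_loocv: float
    per_celltype_predictions: pd.DataFrame  # columns: cell_type, observed, predicted
    r2_transfer: float = float("nan")
    r2_shuffled: float = float("nan")
    bootstrap_r2: list[float] = field(default_factory=list)


def _transform_target(y: pd.Series, prop: str | None) -> tuple[pd.Series, str]:
    if prop is None:
        return y.astype(float), "identity"
    check_property(prop)
    if prop in LOG10_PROPERTIES:
        return pd.Series(to_model_scale(prop, y.to_numpy()), index=y.index), "log10"
    return y.astype(float), "identity"


def _inner_cv(n: int, seed: int, loo: bool):
    """Penalty-selection folds.  Stage 1 (thousands of candidate genes)
    uses seeded 10-fold, the glmnet cv default the reference analysis
    used; stage 2 (a handful of selected genes) uses leave-one-out, whose
    lower-variance error curve gives a steadier penalty at small n for
    negligible cost.  LOO is also used whenever n is too small to populate
    10 folds."""
    if loo or n < 12:
        return list(LeaveOneOut().split(np.zeros((n, 1))))
    return list(
        KFold(n_splits=10, shuffle=True, random_state=seed % (2**31)).split(
            np.zeros((n, 1))
        )
    )


def _enet_cv(
    Xs: np.ndarray, y: np.ndarray, cfg: RunConfig, seed: int, loo: bool = False
) -> ElasticNetCV:
    model = ElasticNetCV(
        l1_ratio=cfg.enet_alpha,
        alphas=cfg.enet_nlambda,
        cv=_inner_cv(len(y), seed, loo),
        fit_intercept=True,
        max_iter=3000,
        tol=3e-4,
    )
    model.fit(Xs, y)
    return model


def fit_two_stage(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: RunConfig,
    prop: str | None = None,
    standardize_y: bool = False,
) -> SparseEphysModel:
    """Fit the two-stage sparse elastic-net model.

    ``X`` is cell_type x gene raw expression; ``y`` holds the property's
    native-unit values (NaN rows are dropped; log10 set transformed per
    registry when ``prop`` is given).  Gene z-scoring statistics are
    derived from the training rows and stored.  Stage 1 runs the elastic
    net over the full gene set and keeps the nonzero-coefficient genes;
    stage 2 repeats the penalized CV procedure restricted to them.  A
    constant target yields an intercept-only model with a warning.

    ``standardize_y`` additionally z-scores the (transformed) target and
    stores the scaling -- the setting used for cross-dataset transfer.
    """
    y = y.dropna()
    X = X.loc[y.index]
    n = len(y)
    if n < 8:
        raise ValueError(f"need >= 8 cell types to fit, have {n}")
    y_t, transform = _transform_target(y, prop)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = sd.where(sd > 0, 1.0)
    scaling = pd.DataFrame({"mean": mean, "sd": sd_safe})
    Xs = ((X - mean) / sd_safe).to_numpy(dtype=float)

    y_scaling = None
    yv = y_t.to_numpy(dtype=float)
    if standardize_y:
        mu, sdy = float(yv.mean()), float(yv.std(ddof=0))
        if sdy > 0:
            yv = (yv - mu) / sdy
            y_scaling = (mu, sdy)
        else:
            y_scaling = (mu, 1.0)

    if np.ptp(yv) == 0:
        logger.warning("fit_two_stage[%s]: constant target; intercept-only model", prop)
        return SparseEphysModel(
            property=prop,
            transform=transform,
            gene_scaling=scaling,
            selected_genes=[],
            coefficients={},
            intercept=float(yv[0]),
            y_scaling=y_scaling,
            fit_meta={"enet_alpha": cfg.enet_alpha, "stage1_genes": 0, "seed": cfg.seed},
        )

    stage1 = _enet_cv(Xs, yv, cfg, cfg.seed)
    selected_idx = np.nonzero(stage1.coef_)[0]
    selected = [X.columns[i] for i in selected_idx]
    if not selected:
        logger.warning("fit_two_stage[%s]: stage 1 selected no genes; intercept-only", prop)
        return SparseEphysModel(
            property=prop,
            transform=transform,
            gene_scaling=scaling,
            selected_genes=[],
            coefficients={},
            intercept=float(yv.mean()),
            y_scaling=y_scaling,
            fit_meta={"enet_alpha": cfg.enet_alpha, "stage1_genes": 0, "seed": cfg.seed},
        )
    stage2 = _enet_cv(Xs[:, selected_idx], yv, cfg, cfg.seed + 1, loo=True)
    coefficients = {g: float(c) for g, c in zip(selected, stage2.coef_)}
    return SparseEphysModel(
        property=prop,
        transform=transform,
        gene_scaling=scaling,
        selected_genes=selected,
        coefficients=coefficients,
        intercept=float(stage2.intercept_),
        y_scaling=y_scaling,
        fit_meta={
            "enet_alpha": cfg.enet_alpha,
            "stage1_genes": len(selected),
            "stage1_lambda": float(stage1.alpha_),
            "stage2_lambda": float(stage2.alpha_),
            "seed": cfg.seed,
        },
    )


def _r2_sse(observed: np.ndarray, predicted: np.ndarray) -> float:
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return float("nan")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


def evaluate_loocv(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: RunConfig,
    prop: str | None = None,
) -> ModelEvaluation:
    """Leave-one-cell-type-out evaluation of the two-stage model.

    Both stages and the per-gene scaling are re-derived inside each fold;
    R2 is computed over the pooled held-out predictions on the modeling
    scale (1 - SSE/SST; can be negative).
    """
    y = y.dropna()
    X = X.loc[y.index]
    if len(y) < 8:
        raise ValueError(f"need >= 8 cell types for LOOCV, have {len(y)}")
    y_t, _ = _transform_target(y, prop)
    preds = []
    for held_out in y.index:
        train = y.index != held_out
        model = fit_two_stage(X.loc[train], y[train], cfg, prop=prop)
        pred = float(model.predict(X.loc[[held_out]])[0])
        preds.append((held_out, float(y_t[held_out]), pred))
    table = pd.DataFrame(preds, columns=["cell_type", "observed", "predicted"])
    r2 = _r2_sse(table["observed"].to_numpy(), table["predicted"].to_numpy())
    return ModelEvaluation(property=prop, r2_loocv=r2, per_celltype_predictions=table)


def shuffled_label_null(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: RunConfig,
    prop: str | None = None,
    n_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[float]]:
    """Chance-level LOOCV performance: the target is randomly re-paired
    with the expression rows once per replicate and the full LOOCV re-run.
    Returns (median shuffled R2, all replicate R2 values)."""
    if rng is None:
        rng = substream(cfg.seed, f"shuffled-null:{prop}")
    y = y.dropna()
    r2s = []
    for _ in range(n_replicates):
        perm = rng.permutation(len(y))
        y_shuf = pd.Series(y.to_numpy()[perm], index=y.index)
        r2s.append(evaluate_loocv(X, y_shuf, cfg, prop=prop).r2_loocv)
    return float(np.median(r2s)), r2s


def bootstrap_performance(
    raw_expr: ExpressionMatrix,
    raw_ephys_records: Sequence[EphysMeasurement],
    cfg: RunConfig,
    prop: str,
    n_bootstrap: int | None = None,
    rng: np.random.Generator | None = None,
    fixed_thresholds: tuple[float, float] | None = None,
) -> list[float]:
    """Bootstrap LOOCV R2 over resamples of the pre-summarization data.

    Per replicate: expression samples are resampled with replacement
    within each cell type and ephys articles within each (cell type,
    property) stratum -- so every original cell type is present in every
    replicate -- then the paired dataset is rebuilt through the standard
    summarization pipeline and LOOCV re-run.
    """
    check_property(prop)
    if rng is None:
        rng = substream(cfg.seed, f"bootstrap:{prop}")
    if n_bootstrap is None:
        n_bootstrap = cfg.n_bootstrap
    meta = raw_expr.meta_for_samples()
    by_type: dict[str, list[str]] = {}
    for sid, label in meta["cell_type_label"].items():
        by_type.setdefault(label, []).append(sid)
    articles: dict[tuple[str, str], list[str]] = {}
    recs_by_article: dict[tuple[str, str, str], list[EphysMeasurement]] = {}
    raw_ephys_records = preprocess_measurements(raw_ephys_records, cfg)
    for r in raw_ephys_records:
        if r.property != prop:
            continue
        key = (r.cell_type_label, r.property)
        if r.article_id not in articles.setdefault(key, []):
            articles[key].append(r.article_id)
        recs_by_article.setdefault((r.cell_type_label, r.property, r.article_id), []).append(r)

    r2s: list[float] = []
    for b in range(n_bootstrap):
        sample_ids = []
        for label, sids in by_type.items():
            take = rng.integers(0, len(sids), size=len(sids))
            sample_ids.extend(sids[i] for i in take)
        values = raw_expr.values[sample_ids].copy()
        values.columns = [f"b{b}_{i}" for i in range(len(sample_ids))]
        new_meta = meta.loc[sample_ids].copy()
        new_meta.index = values.columns
        expr_b = ExpressionMatrix(values=values, scale=raw_expr.scale, sample_meta=new_meta)
        celltype_expr = summarize_expression_by_cell_type(expr_b)
        filtered, _ = filter_genes(celltype_expr, fixed_thresholds=fixed_thresholds)

        boot_records: list[EphysMeasurement] = []
        for (label, p), arts in articles.items():
            take = rng.integers(0, len(arts), size=len(arts))
            for j, i in enumerate(take):
                for r in recs_by_article[(label, p, arts[i])]:
                    boot_records.append(
                        dataclasses.replace(r, article_id=f"b{b}_{j}_{r.article_id}")
                    )
        ephys_b = summarize_ephys_by_cell_type(boot_records)

        common = filtered.index.intersection(ephys_b.index)
        yb = ephys_b.loc[common, prop]
        r2s.append(evaluate_loocv(filtered.loc[common], yb, cfg, prop=prop).r2_loocv)
    return r2s


def transfer_predict(
    model: SparseEphysModel,
    val_expr: pd.DataFrame,
    val_ephys: pd.Series,
    cfg: RunConfig,
    expr_scale: str = "tpm",
) -> tuple[pd.DataFrame, float, float]:
    """Apply a discovery-trained model to an independently normalized
    validation dataset.

    Validation expression (line x gene) is mapped to log2(TPM+1) when
    ``expr_scale`` is "tpm" (use "log2" for data already on a log scale)
    and z-scored per gene *within the validation dataset*; validation
    ephys is registry-transformed then z-scored within dataset.  The model
    must have been fit on a standardized target (``standardize_y=True``)
    so predictions and observations share the standardized scale.

    Returns (per-line prediction table, squared-Pearson R2 -- the headline
    transfer metric, tolerant of affine miscalibration -- and the
    unity-line 1 - SSE/SST form).
    """
    if model.y_scaling is None:
        raise ValueError("transfer requires a model fit with standardize_y=True")
    missing = [g for g in model.selected_genes if g not in val_expr.columns]
    if missing:
        raise ValueError(f"model genes absent from validation expression: {missing}")
    val_ephys = val_ephys.dropna()
    X = val_expr.loc[val_ephys.index]
    if expr_scale == "tpm":
        X = np.log2(X + 1.0)
    elif expr_scale != "log2":
        raise ValueError("expr_scale must be 'tpm' or 'log2'")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Xz = (X - mean) / sd.where(sd > 0, 1.0)

    if model.selected_genes:
        beta = np.array([model.coefficients[g] for g in model.selected_genes])
        pred = Xz[model.selected_genes].to_numpy(dtype=float) @ beta + model.intercept
    else:
        pred = np.full(len(Xz), model.intercept)

    y_t, _ = _transform_target(val_ephys, model.property)
    yv = y_t.to_numpy(dtype=float)
    sdy = yv.std(ddof=0)
    y_z = (yv - yv.mean()) / (sdy if sdy > 0 else 1.0)

    table = pd.DataFrame(
        {"cell_type": val_ephys.index, "observed": y_z, "predicted": pred}
    )
    if np.ptp(pred) == 0 or np.ptp(y_z) == 0:
        r2_pearson = float("nan")
    else:
        r2_pearson = float(np.corrcoef(y_z, pred)[0, 1] ** 2)
    r2_sse = _r2_sse(y_z, pred)
    return table, r2_pearson, r2_sse
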
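"""Univariate gene--ephys correlation screening and cross-dataset
consistency.

For every gene and every ephys property, the screen computes a Spearman
rank correlation across the cell types with that property observed, a
two-sided p-value from the t approximation, and a Benjamini--Hochberg
adjusted p-value (FDR) computed within property only -- properties are
correlated with one another, so no further correction is applied across
properties.

Cross-dataset consistency between a discovery screen and a validation
screen is quantified two ways: the overall Spearman correlation between
the two full r_s vectors, and, for discovery hits (p_adj < 0.05), the
percentage whose validation correlation matches in sign with |r_s| above a
threshold (default 0.3).  Both statistics get permutation p-values from
re-pairing cell-type labels between the validation ephys and expression
rows (default 1000 shuffles, add-one smoothing: p = (1 + #{null >=
observed}) / (B + 1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel_io import (
    PairedCellTypeDataset,
    RunConfig,
    check_property,
    substream,
)

logger = logging.getLogger("genephys.correlation_screen")

__all__ = [
    "ConsistencyResult",
    "spearman_with_p",
    "bh_adjust",
    "screen",
    "significance_counts",
    "consistency_overall",
    "consistency_per_gene",
    "permutation_null",
    "merge_screen_tables",
    "compare_datasets",
]

#: Columns of the per-(gene, property) correlation record table.
RECORD_COLUMNS = ["gene", "property", "n_celltypes", "r_s", "p_value", "p_adj"]


@dataclass
class ConsistencyResult:
    """Per-property cross-dataset consistency summary (Table-3-style row)."""

    property: str
    overall_rho: float
    overall_p: float
    n_discovered: int
    n_consistent: int
    pct_consistent: float
    consistency_p: float


# ---------------------------------------------------------------------------
# Primitive statistics
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, method="average", axis=axis)


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman r via the t approximation on n-2 df; |r|=1
    is reported as the smallest representable positive value."""
    r = np.clip(r, -1.0, 1.0)
    p = np.empty_like(r, dtype=float)
    extreme = np.isclose(np.abs(r), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p[~extreme] = 2.0 * stats.t.sf(np.abs(t[~extreme]), df=n - 2)
    p[extreme] = np.nextafter(0, 1)
    return np.minimum(p, 1.0)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Average-rank Spearman correlation and its two-sided t-approximation
    p-value (the reference implementation's tie behavior).

    Zero variance in either input leaves the correlation undefined: the
    result is (nan, nan), logged, and callers exclude it downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman_with_p: zero variance; correlation undefined")
        return float("nan"), float("nan")
    rx, ry = _rank(x), _rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return r, float(_t_pvalue(np.array([r]), len(x))[0])


def bh_adjust(p) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

def _property_correlations(
    expression: pd.DataFrame, y: pd.Series
) -> tuple[pd.Index, np.ndarray, int]:
    """Spearman r_s of every gene against one property over complete cell
    types; constant genes are excluded (returned index covers kept genes)."""
    mask = y.notna()
    n = int(mask.sum())
    E = expression.loc[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    rank_E = _rank(E, axis=0)
    keep = rank_E.std(axis=0) > 0
    if np.ptp(yv) == 0:
        keep[:] = False
    genes = expression.columns[keep]
    if not keep.any():
        return genes, np.empty(0), n
    RE = rank_E[:, keep] - rank_E[:, keep].mean(axis=0)
    ry = _rank(yv)
    ry = ry - ry.mean()
    denom = np.sqrt((RE**2).sum(axis=0) * (ry @ ry))
    r = (ry @ RE) / denom
    return genes, np.clip(r, -1.0, 1.0), n


def screen(dataset: PairedCellTypeDataset, cfg: RunConfig) -> pd.DataFrame:
    """Per-gene Spearman screen of every property, BH-adjusted within
    property.

    Properties with fewer complete cell types than
    ``cfg.min_celltypes_per_property`` are skipped with a warning; genes
    constant across the complete cell types are excluded (logged).
    Returns a record table with columns ``gene, property, n_celltypes,
    r_s, p_value, p_adj``.
    """
    frames = []
    for prop in dataset.ephys.columns:
        y = dataset.ephys[prop]
        n = int(y.notna().sum())
        if n < cfg.min_celltypes_per_property:
            logger.warning(
                "screen: %s has %d complete cell types (< %d); skipped",
                prop, n, cfg.min_celltypes_per_property,
            )
            continue
        genes, r, n = _property_correlations(dataset.expression, y)
        n_const = dataset.expression.shape[1] - len(genes)
        if n_const:
            logger.info("screen[%s]: excluded %d constant genes", prop, n_const)
        if len(genes) == 0:
            logger.warning("screen: no testable genes for %s; skipped", prop)
            continue
        p = _t_pvalue(r, n)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "property": prop,
                    "n_celltypes": n,
                    "r_s": r,
                    "p_value": p,
                    "p_adj": bh_adjust(p),
                }
            )
        )
    if not frames:
        raise ValueError("no property had enough complete cell types to screen")
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    for alpha, count in significance_counts(records, cfg.bh_alpha_levels)["genes"].items():
        logger.info("screen: %d genes significant for >= 1 property at p_adj < %g", count, alpha)
    return records


def significance_counts(
    records: pd.DataFrame, alphas=(0.01, 0.05, 0.1)
) -> dict[str, pd.Series | pd.DataFrame]:
    """Summary counts: per-property significant genes at each FDR level, and
    the number of unique genes significant for at least one property."""
    per_property = pd.DataFrame(
        {
            alpha: records[records["p_adj"] < alpha].groupby("property")["gene"].nunique()
            for alpha in alphas
        }
    ).reindex(sorted(records["property"].unique())).fillna(0).astype(int)
    genes = pd.Series(
        {alpha: records.loc[records["p_adj"] < alpha, "gene"].nunique() for alpha in alphas}
    )
    return {"per_property": per_property, "genes": genes}


# ---------------------------------------------------------------------------
# Cross-dataset consistency
# ---------------------------------------------------------------------------

def _records_for(records: pd.DataFrame, prop: str) -> pd.Series:
    sub = records[records["property"] == prop]
    return sub.set_index("gene")["r_s"]


def consistency_overall(
    disc: pd.DataFrame, val: pd.DataFrame, prop: str
) -> float:
    """Spearman correlation between the discovery and validation r_s vectors
    over their common genes (undefined correlations excluded pairwise)."""
    check_property(prop)
    r_d = _records_for(disc, prop).dropna()
    r_v = _records_for(val, prop).dropna()
    common = r_d.index.intersection(r_v.index)
    if len(common) < 10:
        raise ValueError(
            f"{prop}: only {len(common)} genes in common; need >= 10 for "
            "overall consistency"
        )
    rho, _ = spearman_with_p(r_d[common].to_numpy(), r_v[common].to_numpy())
    return rho


def consistency_per_gene(
    disc: pd.DataFrame,
    val: pd.DataFrame,
    cfg: RunConfig,
    prop: str,
    discovery_alpha: float = 0.05,
) -> tuple[list[str], float, list[str]]:
    """Which discovery hits replicate: a discovered (gene, property) with
    p_adj < ``discovery_alpha`` is consistent iff the validation correlation
    has the same sign and |r_s| > ``cfg.consistency_abs_r``.

    Returns (consistent genes, percentage consistent among evaluable hits,
    genes not evaluable because they are absent from the validation screen).
    """
    check_property(prop)
    sub = disc[(disc["property"] == prop) & (disc["p_adj"] < discovery_alpha)]
    r_v = _records_for(val, prop)
    consistent, not_evaluable = [], []
    n_eval = 0
    for gene, r_d in zip(sub["gene"], sub["r_s"]):
        if gene not in r_v.index or np.isnan(r_v[gene]):
            not_evaluable.append(gene)
            continue
        n_eval += 1
        rv = r_v[gene]
        if np.sign(rv) == np.sign(r_d) and abs(rv) > cfg.consistency_abs_r:
            consistent.append(gene)
    pct = 100.0 * len(consistent) / n_eval if n_eval else float("nan")
    return consistent, pct, not_evaluable


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _null_correlation_matrix(
    dataset: PairedCellTypeDataset,
    prop: str,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Observed r_s per gene plus a B x G matrix of label-shuffled r_s.

    Each shuffle re-pairs the ephys rows with the expression rows of the
    complete cell types, leaving each modality's internal structure intact.
    """
    y = dataset.ephys[prop]
    mask = y.notna()
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"{prop}: fewer than 4 complete cell types; permutation degenerate")
    genes, r_obs, _ = _property_correlations(dataset.expression, y)
    E = dataset.expression.loc[mask.to_numpy(), genes].to_numpy(dtype=float)
    RE = _rank(E, axis=0)
    RE = RE - RE.mean(axis=0)
    norm_E = np.sqrt((RE**2).sum(axis=0))
    ry = _rank(y[mask].to_numpy(dtype=float))
    ry = ry - ry.mean()
    norm_y = np.sqrt(ry @ ry)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Y = ry[perms]  # B x n
    null_r = (Y @ RE) / (norm_y * norm_E)
    return genes, r_obs, np.clip(null_r, -1.0, 1.0)


def _overall_rho_stat(r_disc: np.ndarray, r_val: np.ndarray) -> float:
    rd = _rank(r_disc)
    rv = _rank(r_val)
    rd = rd - rd.mean()
    rv = rv - rv.mean()
    return float(rd @ rv / np.sqrt((rd @ rd) * (rv @ rv)))


def permutation_null(
    val_dataset: PairedCellTypeDataset,
    disc: pd.DataFrame,
    statistic: str,
    cfg: RunConfig,
    prop: str,
    discovery_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, float]:
    """Permutation test of a cross-dataset consistency statistic.

    ``statistic`` is ``"overall_rho"`` (rank correlation of the two full
    r_s vectors) or ``"pct_consistent"`` (percentage of discovery hits
    replicating under the sign + |r_s| > threshold rule).  Validation
    cell-type labels are re-paired between ephys and expression
    ``cfg.n_permutations`` times; the one-sided p-value uses add-one
    smoothing, so an observed value above every null reports
    1/(B+1) -- "< 0.001" at B = 1000.

    Returns (observed, null distribution, p).
    """
    if statistic not in ("overall_rho", "pct_consistent"):
        raise ValueError(f"unknown statistic {statistic!r}")
    check_property(prop)
    if cfg.n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = substream(cfg.seed, f"permutation:{prop}:{statistic}")
    genes, r_val_obs, null_r = _null_correlation_matrix(
        val_dataset, prop, cfg.n_permutations, rng
    )
    r_val = pd.Series(r_val_obs, index=genes)

    if statistic == "overall_rho":
        r_d = _records_for(disc, prop).dropna()
        common = r_d.index.intersection(genes)
        if len(common) < 10:
            raise ValueError(f"{prop}: fewer than 10 common genes")
        pos = pd.Series(np.arange(len(genes)), index=genes)[common].to_numpy()
        rd = r_d[common].to_numpy()
        observed = _overall_rho_stat(rd, r_val[common].to_numpy())
        sub_null = null_r[:, pos]
        rank_d = _rank(rd)
        rank_d = rank_d - rank_d.mean()
        rank_null = _rank(sub_null, axis=1)
        rank_null = rank_null - rank_null.mean(axis=1, keepdims=True)
        null = (rank_null @ rank_d) / np.sqrt(
            (rank_null**2).sum(axis=1) * (rank_d @ rank_d)
        )
    else:
        sub = disc[(disc["property"] == prop) & (disc["p_adj"] < discovery_alpha)]
        sub = sub[sub["gene"].isin(genes)]
        if len(sub) == 0:
            raise ValueError(f"{prop}: no evaluable discovery hits at p_adj < {discovery_alpha}")
        pos = pd.Series(np.arange(len(genes)), index=genes)[sub["gene"]].to_numpy()
        sign_d = np.sign(sub["r_s"].to_numpy())
        thr = cfg.consistency_abs_r
        rv = r_val.iloc[pos].to_numpy()
        observed = 100.0 * np.mean((np.sign(rv) == sign_d) & (np.abs(rv) > thr))
        sub_null = null_r[:, pos]
        null = 100.0 * np.mean(
            (np.sign(sub_null) == sign_d) & (np.abs(sub_null) > thr), axis=1
        )

    p = (1.0 + np.sum(null >= observed)) / (cfg.n_permutations + 1.0)
    return float(observed), null, float(p)


def merge_screen_tables(
    disc: pd.DataFrame,
    val: pd.DataFrame,
    cfg: RunConfig,
    discovery_alpha: float = 0.05,
) -> pd.DataFrame:
    """Merged per-(property, gene) table of discovery and validation
    screens with the replication flag -- the supplementary-table layout:
    EphysProp, Gene, DiscCorr/DiscUncorrPval/DiscFDR,
    ValCorr/ValUncorrPval/ValFDR, Consistent."""
    d = disc.rename(
        columns={"r_s": "DiscCorr", "p_value": "DiscUncorrPval", "p_adj": "DiscFDR"}
    )[["property", "gene", "DiscCorr", "DiscUncorrPval", "DiscFDR"]]
    v = val.rename(
        columns={"r_s": "ValCorr", "p_value": "ValUncorrPval", "p_adj": "ValFDR"}
    )[["property", "gene", "ValCorr", "ValUncorrPval", "ValFDR"]]
    merged = d.merge(v, on=["property", "gene"], how="left")
    merged["Consistent"] = (
        (merged["DiscFDR"] < discovery_alpha)
        & (np.sign(merged["ValCorr"]) == np.sign(merged["DiscCorr"]))
        & (merged["ValCorr"].abs() > cfg.consistency_abs_r)
    ).fillna(False)
    return merged.rename(columns={"property": "EphysProp", "gene": "Gene"})


def compare_datasets(
    disc: pd.DataFrame,
    val_dataset: PairedCellTypeDataset,
    cfg: RunConfig,
    discovery_alpha: float = 0.05,
) -> list[ConsistencyResult]:
    """Full per-property consistency table between a discovery screen and a
    validation dataset (overall rho + replication percentage, each with a
    permutation p-value)."""
    val_records = screen(val_dataset, cfg)
    results = []
    props = [p for p in disc["property"].unique() if p in set(val_records["property"])]
    for prop in props:
        rho, _, rho_p = permutation_null(val_dataset, disc, "overall_rho", cfg, prop)
        sub = disc[(disc["property"] == prop) & (disc["p_adj"] < discovery_alpha)]
        val_genes = set(_records_for(val_records, prop).dropna().index)
        n_disc = int(sub["gene"].isin(val_genes).sum())
        if n_disc == 0:
            results.append(
                ConsistencyResult(prop, rho, rho_p, 0, 0, float("nan"), float("nan"))
            )
            continue
        consistent, pct, _ = consistency_per_gene(
            disc, val_records, cfg, prop, discovery_alpha
        )
        _, _, pct_p = permutation_null(
            val_dataset, disc, "pct_consistent", cfg, prop, discovery_alpha
        )
        results.append(
            ConsistencyResult(prop, rho, rho_p, n_disc, len(consistent), pct, pct_p)
        )
    return results
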
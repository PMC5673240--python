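"""Expression preprocessing: quantile normalization, probe collapse,
cell-type summarization, mean/variance gene filtering, single-cell
aggregation.

Turns sample-level expression into the filtered cell-type-level matrix the
correlation screen and predictive models consume.  The gene filter keeps
genes that are both highly expressed and highly variable across cell types:
mu_g > mean(mu) and sigma_g > mean(sigma), where mu_g/sigma_g are each
gene's mean and (n-1) standard deviation across the cell-type summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel_io import ExpressionMatrix

logger = logging.getLogger("genephys.expression_prep")

__all__ = [
    "GeneFilterThresholds",
    "quantile_normalize",
    "collapse_probes_to_genes",
    "summarize_expression_by_cell_type",
    "filter_genes",
    "aggregate_single_cells",
]


@dataclass
class GeneFilterThresholds:
    """Per-gene means/SDs across cell types and the derived global cutoffs."""

    mu_global: float
    sigma_global: float
    per_gene_mu: pd.Series
    per_gene_sigma: pd.Series


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's empirical distribution onto the cross-sample
    mean of order statistics; tied values receive the average of the tied
    positions' target values, so identical inputs stay identical.
    """
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    positions = np.arange(vals.shape[0], dtype=float)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, scale=m.scale, sample_meta=m.sample_meta)


def collapse_probes_to_genes(
    m: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """One row per gene: for multi-probe genes keep the probe with the
    largest across-sample variance (ties broken by input order, logged);
    probes absent from the mapping are dropped with a logged count.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    probes = list(m.values.index)
    mapped = [p for p in probes if p in probe_to_gene]
    n_dropped = len(probes) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probes", n_dropped)
    variances = m.values.loc[mapped].var(axis=1, ddof=1)
    best: dict[str, tuple[str, float]] = {}
    gene_order: list[str] = []
    for p in mapped:
        g = probe_to_gene[p]
        v = float(variances[p])
        if g not in best:
            best[g] = (p, v)
            gene_order.append(g)
        elif v > best[g][1]:
            best[g] = (p, v)
        elif v == best[g][1]:
            logger.info(
                "collapse_probes_to_genes: variance tie for gene %s between "
                "probes %s and %s; keeping the first", g, best[g][0], p,
            )
    chosen = [best[g][0] for g in gene_order]
    values = m.values.loc[chosen].copy()
    values.index = pd.Index(gene_order, name="gene")
    return ExpressionMatrix(values=values, scale=m.scale, sample_meta=m.sample_meta)


def summarize_expression_by_cell_type(m: ExpressionMatrix) -> pd.DataFrame:
    """Cell-type x gene matrix of per-gene arithmetic means over the samples
    carrying each cell-type label; per-type sample counts are logged."""
    meta = m.meta_for_samples()
    labels = meta["cell_type_label"]
    if labels.isna().any():
        missing = list(meta.index[labels.isna()])
        raise ValueError(f"samples without cell_type_label: {missing}")
    summary = m.values.T.groupby(labels.to_numpy()).mean()
    summary.index.name = "cell_type"
    counts = labels.value_counts()
    logger.info(
        "summarize_expression_by_cell_type: %d cell types, sample counts %s",
        summary.shape[0], counts.to_dict(),
    )
    return summary


def filter_genes(
    celltype_expr: pd.DataFrame,
    fixed_thresholds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, GeneFilterThresholds]:
    """Keep genes with mu_g above the global mean of means AND sigma_g above
    the global mean of SDs (sample SD, ddof=1, across cell types).

    ``fixed_thresholds`` replaces the derived (mu_global, sigma_global)
    cutoffs with externally supplied values, under which the filter is
    idempotent.
    """
    if celltype_expr.shape[0] < 2:
        raise ValueError("gene filtering needs at least 2 cell types")
    mu_g = celltype_expr.mean(axis=0)
    sigma_g = celltype_expr.std(axis=0, ddof=1)
    if fixed_thresholds is not None:
        mu_global, sigma_global = map(float, fixed_thresholds)
    else:
        mu_global = float(mu_g.mean())
        sigma_global = float(sigma_g.mean())
    keep = (mu_g > mu_global) & (sigma_g > sigma_global)
    if not keep.any():
        raise ValueError(
            f"all genes filtered out (mu_global={mu_global:.3g}, "
            f"sigma_global={sigma_global:.3g})"
        )
    logger.info(
        "filter_genes: retained %d of %d genes (mu_global=%.4g, sigma_global=%.4g)",
        int(keep.sum()), len(keep), mu_global, sigma_global,
    )
    thresholds = GeneFilterThresholds(
        mu_global=mu_global,
        sigma_global=sigma_global,
        per_gene_mu=mu_g,
        per_gene_sigma=sigma_g,
    )
    return celltype_expr.loc[:, keep], thresholds


def aggregate_single_cells(
    m: ExpressionMatrix,
    min_cells: int,
    ephys_cell_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Summarize single cells to line x gene mean TPM, excluding lines with
    fewer than ``min_cells`` cells in either modality.

    ``ephys_cell_counts`` (line -> cell count) applies the same floor on the
    ephys side when supplied; lines absent from it count as 0.  The
    exclusion list is logged.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    meta = m.meta_for_samples()
    labels = meta["cell_type_label"]
    counts = labels.value_counts()
    excluded: list[str] = [line for line, c in counts.items() if c < min_cells]
    if ephys_cell_counts is not None:
        for line in counts.index:
            if int(ephys_cell_counts.get(line, 0)) < min_cells and line not in excluded:
                excluded.append(line)
    kept = [line for line in counts.index if line not in excluded]
    if not kept:
        raise ValueError(f"no line has >= {min_cells} cells in every modality")
    if excluded:
        logger.info(
            "aggregate_single_cells: excluded %d lines below %d cells: %s",
            len(excluded), min_cells, sorted(excluded),
        )
    mask = labels.isin(kept).to_numpy()
    sub = m.values.loc[:, mask]
    summary = sub.T.groupby(labels[mask].to_numpy()).mean()
    summary.index.name = "line"
    return summary
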
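"""Pairing expression cell types with ephys cell types.

The mapping between transcriptomic labels (e.g. a transgenic-line-defined
population) and literature ephys labels (morpho-electric criteria) is
semantic curation and is therefore supplied explicitly, never inferred from
strings.  Developmental subtypes defined at different ages are paired only
when their annotated ages agree within a tolerance (default +/- 2.5 days).
"""

from __future__ import annotations

import logging

import pandas as pd

from .datamodel_io import PairedCellTypeDataset, RunConfig

logger = logging.getLogger("genephys.harmonize")

__all__ = ["align_datasets", "intersect_genes", "read_mapping"]


def read_mapping(path) -> pd.DataFrame:
    """Read a two-column (expression_label, ephys_label) mapping table,
    optionally with a third ``age_days`` column."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"expression_label", "ephys_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping file must have columns {sorted(required)}")
    return df


def align_datasets(
    expr: pd.DataFrame,
    ephys: pd.DataFrame,
    mapping: pd.DataFrame,
    cfg: RunConfig,
    expr_ages: pd.Series | None = None,
    ephys_ages: pd.Series | None = None,
) -> PairedCellTypeDataset:
    """Build the paired cell-type dataset from an explicit label mapping.

    ``expr`` is cell_type x gene, ``ephys`` is cell_type x property;
    ``mapping`` has columns expression_label / ephys_label.  When both
    sides carry an age annotation for a pair, the pair is kept only if the
    ages agree within ``cfg.age_match_tolerance_days``; pairs lacking an
    age on either side match on label alone.  Unmatched labels are listed
    in the dataset's provenance.
    """
    if not set(mapping["expression_label"]).issubset(expr.index):
        missing = sorted(set(mapping["expression_label"]) - set(expr.index))
        raise ValueError(f"mapping expression labels absent from matrix: {missing}")
    if not set(mapping["ephys_label"]).issubset(ephys.index):
        missing = sorted(set(mapping["ephys_label"]) - set(ephys.index))
        raise ValueError(f"mapping ephys labels absent from table: {missing}")

    rows_expr, rows_ephys, provenance = [], [], {}
    # sort for order-independence of the pairing set
    pairs = mapping[["expression_label", "ephys_label"]].drop_duplicates()
    pairs = pairs.sort_values(list(pairs.columns)).itertuples(index=False)
    for e_label, p_label in pairs:
        a_expr = None if expr_ages is None else expr_ages.get(e_label)
        a_ephys = None if ephys_ages is None else ephys_ages.get(p_label)
        if (
            a_expr is not None
            and a_ephys is not None
            and not (pd.isna(a_expr) or pd.isna(a_ephys))
            and abs(float(a_expr) - float(a_ephys)) > cfg.age_match_tolerance_days
        ):
            provenance[str(e_label)] = (
                f"dropped: age mismatch ({a_expr:g} vs {a_ephys:g} days, "
                f"tolerance {cfg.age_match_tolerance_days:g})"
            )
            continue
        rows_expr.append(e_label)
        rows_ephys.append(p_label)
    if not rows_expr:
        raise ValueError("no cell-type pairs survive mapping and age matching")

    expression = expr.loc[rows_expr].copy()
    ephys_part = ephys.loc[rows_ephys].copy()
    ephys_part.index = expression.index
    for label in provenance:
        logger.info("align_datasets: %s -> %s", label, provenance[label])
    logger.info("align_datasets: paired %d cell types", len(rows_expr))
    return PairedCellTypeDataset(
        expression=expression, ephys=ephys_part, provenance=provenance
    )


def intersect_genes(
    a: PairedCellTypeDataset, b: pd.DataFrame
) -> tuple[PairedCellTypeDataset, pd.DataFrame]:
    """Restrict a paired dataset and a second cell_type x gene matrix to
    their common genes, column-aligned in sorted order."""
    common = sorted(set(a.genes) & set(b.columns))
    if not common:
        raise ValueError("no genes in common between the two datasets")
    logger.info(
        "intersect_genes: %d common genes (from %d and %d)",
        len(common), len(a.genes), b.shape[1],
    )
    a2 = PairedCellTypeDataset(
        expression=a.expression[common].copy(),
        ephys=a.ephys.copy(),
        provenance=dict(a.provenance),
    )
    return a2, b[common].copy()
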
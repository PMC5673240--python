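import warnings

import numpy as np
import pandas as pd
import pytest

import genephys as gp

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


@pytest.fixture(scope="session")
def rc() -> gp.RunConfig:
    return gp.RunConfig(seed=7)


@pytest.fixture()
def tiny_expr() -> gp.ExpressionMatrix:
    """3 features x 4 samples, two cell types."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.5, 2.5, 2.5, 2.5]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {"cell_type_label": ["A", "A", "B", "B"], "age_days": [14, 14, 60, 60]},
        index=values.columns,
    )
    return gp.ExpressionMatrix(values=values, scale="log2_intensity", sample_meta=meta)


@pytest.fixture(scope="session")
def discovery_bundle():
    """A modest shared discovery dataset with strong planted Vrest/Rin signal.

    Session-scoped: several screening/consistency tests reuse it read-only.
    """
    cfg = gp.SyntheticConfig(seed=11, n_cell_types=24, n_genes=400, n_lines=12)
    truth = gp.default_ground_truth(
        cfg,
        n_planted_per_property=12,
        properties=["Vrest", "Rin"],
        target_range=(0.8, 0.9),
        lab_effects=[],
    )
    expr, recs, truth = gp.generate_discovery_dataset(cfg, truth)
    run = gp.RunConfig(seed=11)
    celltype = gp.summarize_expression_by_cell_type(expr)
    ephys = gp.summarize_ephys_by_cell_type(gp.preprocess_measurements(recs, run))
    ds = gp.PairedCellTypeDataset(
        expression=celltype, ephys=ephys.reindex(celltype.index)
    )
    records = gp.screen(ds, run)
    return {
        "cfg": cfg,
        "truth": truth,
        "expr": expr,
        "recs": recs,
        "run": run,
        "dataset": ds,
        "records": records,
    }


@pytest.fixture(scope="session")
def validation_bundle(discovery_bundle):
    """Validation dataset sharing the discovery bundle's ground truth."""
    cfg = discovery_bundle["cfg"]
    truth = discovery_bundle["truth"]
    vexpr, vcells = gp.generate_validation_dataset(cfg, truth)
    lines = gp.aggregate_single_cells(vexpr, min_cells=10)
    vephys = vcells.groupby("cell_type_label")[list(gp.PROPERTY_CODES)].mean()
    vds = gp.PairedCellTypeDataset(
        expression=np.log2(lines + 1.0), ephys=vephys.reindex(lines.index)
    )
    return {"expr": vexpr, "cells": vcells, "dataset": vds}
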
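"""Synthetic paired expression/ephys datasets with known ground truth.

The generator emulates the structure of the real analysis problem: a
"discovery"-style dataset (pooled-cell microarray expression replicates per
cell type, plus article-level literature ephys measurements contaminated by
study-level experimental conditions) and a "validation"-style dataset
(single-cell TPM counts with dropout, grouped by transgenic line, plus
per-cell ephys values), both driven by the same latent cell-type biology so
that cross-dataset consistency is a recoverable target.

Planted gene--ephys relationships are monotone (linear in the latent
property value on the log2 expression scale) and calibrated so that the
population Spearman magnitude across cell types matches a requested target.
Null genes sit at the background expression floor and are independent of
every latent property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel_io import (
    EphysMeasurement,
    ExpressionMatrix,
    LOG10_PROPERTIES,
    PROPERTY_CODES,
    VOLTAGE_PROPERTIES,
    check_property,
    from_model_scale,
    substream,
)

__all__ = [
    "PlantedEffect",
    "LabEffect",
    "GroundTruth",
    "SyntheticConfig",
    "default_ground_truth",
    "generate_discovery_dataset",
    "generate_validation_dataset",
    "save_ground_truth",
]


# Latent cell-type distributions per property, on the modeling scale
# (log10 units for the log10-transformed set, native units otherwise).
# Means/spreads are chosen to resemble intracellular recordings from rodent
# neurons: e.g. Vrest ~ -65 mV, Rin ~ 10^2.2 ~ 160 MOhm.
LATENT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "Vrest": (-65.0, 7.0),
    "Rin": (2.2, 0.45),
    "Tau": (1.2, 0.30),
    "Cm": (1.9, 0.30),
    "APamp": (75.0, 12.0),
    "APhw": (0.0, 0.30),
    "APthr": (-40.0, 4.0),
    "AHPamp": (12.0, 5.0),
    "Rheo": (2.0, 0.45),
    "FRmax": (1.75, 0.40),
    "SFA": (0.65, 0.15),
}

# Article-level measurement noise per property (modeling scale), roughly
# 40% of the between-type latent spread: enough that single articles
# disagree, while per-type medians remain informative.
DEFAULT_MEASUREMENT_NOISE: dict[str, float] = {
    "Vrest": 2.8,
    "Rin": 0.18,
    "Tau": 0.12,
    "Cm": 0.12,
    "APamp": 4.8,
    "APhw": 0.12,
    "APthr": 1.6,
    "AHPamp": 2.0,
    "Rheo": 0.18,
    "FRmax": 0.16,
    "SFA": 0.06,
}

REFERENCE_TEMP_C = 34.0
REFERENCE_LOG10_AGE = 1.5  # ~32 days


@dataclass(frozen=True)
class PlantedEffect:
    """A gene whose expression monotonically tracks one latent property."""

    gene: str
    property: str
    direction: int  # +1 or -1
    target_abs_spearman: float

    def __post_init__(self) -> None:
        check_property(self.property)
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not (0 < self.target_abs_spearman < 1):
            raise ValueError("target_abs_spearman must be in (0, 1)")


@dataclass(frozen=True)
class LabEffect:
    """A study-level condition effect on one property's measurements.

    ``covariate`` is one of {age, temp, electrode, jxn, species}.  For the
    continuous covariates the magnitude is a slope on the modeling scale
    (per degree C, or per log10(day)); for the categorical covariates it is
    an additive offset applied to the non-reference level (sharp electrode,
    not_corrected junction potential, rat).
    """

    property: str
    covariate: str
    magnitude: float

    def __post_init__(self) -> None:
        check_property(self.property)
        if self.covariate not in ("age", "temp", "electrode", "jxn", "species"):
            raise ValueError(f"unknown lab-effect covariate {self.covariate!r}")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, plus realized latents.

    ``latent_ephys`` (cell type x property, modeling scale), ``type_ages``
    and ``type_gene_means`` (cell type x gene, log2 scale) are filled in by
    :func:`generate_discovery_dataset` and consumed by the validation
    generator and by recovery tests.
    """

    planted_effects: list[PlantedEffect]
    lab_effects: list[LabEffect] = field(default_factory=list)
    coexpression_blocks: list[list[str]] = field(default_factory=list)
    null_genes: set[str] = field(default_factory=set)
    latent_ephys: pd.DataFrame | None = None
    type_ages: pd.Series | None = None
    type_gene_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        planted = {e.gene for e in self.planted_effects}
        overlap = planted & self.null_genes
        if overlap:
            raise ValueError(f"planted genes also listed as null: {sorted(overlap)}")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the discovery-study conditions.

    34 cell types with ~3 pooled-cell replicates each, 3000 genes on a log2
    scale with a background floor near 6.0, a handful of literature articles
    per (type, property), and an AIBS-style single-cell mode with dropout.
    """

    n_cell_types: int = 34
    replicates_per_type: int = 3
    n_genes: int = 3000
    background_level: float = 6.0
    articles_per_type_per_property: tuple[int, int] = (3, 8)
    measurement_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_NOISE)
    )
    dropout_rate: float = 0.5
    cells_per_line: int = 40
    n_lines: int = 12
    prop_observed: float = 0.8
    planted_mean: float = 9.0
    planted_type_sd: float = 1.5
    replicate_noise_sd: float = 0.5
    null_type_sd: float = 0.3
    cell_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n_cell_types", "replicates_per_type", "n_genes", "cells_per_line", "n_lines"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be a positive count")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        lo, hi = self.articles_per_type_per_property
        if lo < 1 or hi < lo:
            raise ValueError("articles_per_type_per_property must be a valid positive range")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def cell_type_labels(self) -> list[str]:
        return [f"CT{i:02d}" for i in range(1, self.n_cell_types + 1)]


def default_ground_truth(
    cfg: SyntheticConfig,
    n_planted_per_property: int = 15,
    properties: Sequence[str] | None = None,
    target_range: tuple[float, float] = (0.6, 0.9),
    lab_effects: Sequence[LabEffect] | None = None,
    n_coexpression_blocks: int = 5,
    block_size: int = 20,
) -> GroundTruth:
    """Construct a plausible ground truth for ``cfg``.

    Plants ``n_planted_per_property`` genes per property (disjoint across
    properties) with random sign and target |r_s| uniform in
    ``target_range``, a few co-expression blocks among the null genes, and
    default study-condition effects (temperature and electrode on Vrest,
    age on Rin) unless ``lab_effects`` overrides them.
    """
    rng = substream(cfg.seed, "ground-truth")
    props = list(properties) if properties is not None else list(PROPERTY_CODES)
    genes = cfg.gene_ids()
    needed = n_planted_per_property * len(props)
    if needed > cfg.n_genes:
        raise ValueError("not enough genes to plant the requested effects")
    order = rng.permutation(cfg.n_genes)
    planted: list[PlantedEffect] = []
    k = 0
    for prop in props:
        for _ in range(n_planted_per_property):
            planted.append(
                PlantedEffect(
                    gene=genes[order[k]],
                    property=prop,
                    direction=int(rng.choice([-1, 1])),
                    target_abs_spearman=float(rng.uniform(*target_range)),
                )
            )
            k += 1
    remaining = [genes[i] for i in order[k:]]
    blocks: list[list[str]] = []
    for _ in range(n_coexpression_blocks):
        if len(remaining) < block_size:
            break
        blocks.append(remaining[:block_size])
        remaining = remaining[block_size:]
    null_genes = set(remaining)
    if lab_effects is None:
        lab_effects = [
            LabEffect("Vrest", "temp", 0.5),
            LabEffect("Vrest", "electrode", 6.0),
            LabEffect("Rin", "age", -0.4),
        ]
    return GroundTruth(
        planted_effects=planted,
        lab_effects=list(lab_effects),
        coexpression_blocks=blocks,
        null_genes=null_genes,
    )


def _planted_loading(
    target_abs_spearman: float,
    type_sd: float,
    replicate_sd: float,
    n_replicates: int,
    n_types: int,
) -> float:
    """Pearson loading rho needed so that the *observed* per-type mean
    expression attains the target Spearman magnitude against the latent.

    For a bivariate Gaussian the finite-sample expectation of Spearman's
    statistic is E[r_s] = 6/(pi (n+1)) * ((n-2) asin(rho/2) + asin(rho)),
    which is inverted numerically; replicate-mean noise further attenuates
    the realized correlation by type_sd / sqrt(type_sd^2 + replicate_sd^2/R),
    compensated here.  Raises if the target is unattainable under the
    configured noise.
    """
    n = n_types

    def expected_rs(rho: float) -> float:
        return 6.0 / (np.pi * (n + 1)) * ((n - 2) * np.arcsin(rho / 2) + np.arcsin(rho))

    rho = float(
        brentq(lambda r: expected_rs(r) - target_abs_spearman, 0.0, 1.0)
        if expected_rs(1.0) > target_abs_spearman
        else 1.0
    )
    sem = replicate_sd / np.sqrt(n_replicates)
    attenuation = type_sd / np.sqrt(type_sd**2 + sem**2)
    rho_adj = rho / attenuation
    if rho_adj >= 0.9995:
        raise ValueError(
            f"target |r_s|={target_abs_spearman} is infeasible under "
            f"replicate noise sd={replicate_sd}; lower the noise or the target"
        )
    return float(rho_adj)


def generate_discovery_dataset(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, list[EphysMeasurement], GroundTruth]:
    """Generate a discovery-style dataset and fill in the realized latents.

    Per cell type a latent value of every property is drawn; planted genes'
    per-type mean expression is a linear (hence monotone) function of the
    standardized latent with the requested sign and Spearman-calibrated
    loading; null genes sit at the background floor.  Article-level ephys
    measurements add per-article methodological metadata and the configured
    study-condition effects on the modeling scale.
    """
    genes = cfg.gene_ids()
    gene_set = set(genes)
    for eff in truth.planted_effects:
        if eff.gene not in gene_set:
            raise ValueError(f"planted gene {eff.gene!r} not in the generated gene set")
    types = cfg.cell_type_labels()
    n = cfg.n_cell_types

    meta_rng = substream(cfg.seed, "metadata")
    ephys_rng = substream(cfg.seed, "ephys")
    expr_rng = substream(cfg.seed, "expression")

    # cell-type ages: a quarter developmental (P5-P25), the rest adult
    young = meta_rng.random(n) < 0.25
    ages = np.where(young, meta_rng.uniform(5, 25, n), meta_rng.uniform(40, 80, n))
    type_ages = pd.Series(ages, index=types, name="age_days")

    # latent ephys per type, standardized draws kept for the planted links
    z = pd.DataFrame(
        ephys_rng.standard_normal((n, len(PROPERTY_CODES))),
        index=types,
        columns=list(PROPERTY_CODES),
    )
    latent = pd.DataFrame(index=types, columns=list(PROPERTY_CODES), dtype=float)
    for prop in PROPERTY_CODES:
        mu, sd = LATENT_DISTRIBUTIONS[prop]
        latent[prop] = mu + sd * z[prop]

    # per-type mean expression (log2 scale)
    means = np.empty((n, cfg.n_genes))
    planted_by_gene = {e.gene: e for e in truth.planted_effects}
    block_of: dict[str, int] = {}
    for b, block in enumerate(truth.coexpression_blocks):
        for g in block:
            block_of[g] = b
    factors = expr_rng.standard_normal((n, max(1, len(truth.coexpression_blocks))))
    eta = expr_rng.standard_normal((n, cfg.n_genes))
    for j, g in enumerate(genes):
        eff = planted_by_gene.get(g)
        if eff is not None:
            rho = _planted_loading(
                eff.target_abs_spearman,
                cfg.planted_type_sd,
                cfg.replicate_noise_sd,
                cfg.replicates_per_type,
                cfg.n_cell_types,
            )
            signal = eff.direction * rho * z[eff.property].to_numpy()
            noise = np.sqrt(1.0 - rho**2) * eta[:, j]
            means[:, j] = cfg.planted_mean + cfg.planted_type_sd * (signal + noise)
        elif g in block_of:
            means[:, j] = (
                cfg.background_level
                + 0.8 * factors[:, block_of[g]]
                + cfg.null_type_sd * eta[:, j]
            )
        else:
            means[:, j] = cfg.background_level + cfg.null_type_sd * eta[:, j]

    # replicate samples
    sample_ids, labels, sample_ages = [], [], []
    blocks_vals = []
    for i, t in enumerate(types):
        reps = means[i][None, :] + cfg.replicate_noise_sd * expr_rng.standard_normal(
            (cfg.replicates_per_type, cfg.n_genes)
        )
        blocks_vals.append(reps)
        for r in range(cfg.replicates_per_type):
            sample_ids.append(f"{t}_rep{r + 1}")
            labels.append(t)
            sample_ages.append(ages[i])
    values = pd.DataFrame(
        np.vstack(blocks_vals).T, index=genes, columns=sample_ids
    )
    sample_meta = pd.DataFrame(
        {
            "cell_type_label": labels,
            "age_days": sample_ages,
            "platform": "synthetic_array",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = ExpressionMatrix(values=values, scale="log2_intensity", sample_meta=sample_meta)

    # article-level ephys measurements
    lab_by_prop: dict[str, list[LabEffect]] = {}
    for le in truth.lab_effects:
        lab_by_prop.setdefault(le.property, []).append(le)
    lo, hi = cfg.articles_per_type_per_property
    records: list[EphysMeasurement] = []
    article_counter = 0
    for i, t in enumerate(types):
        observed = ephys_rng.random(len(PROPERTY_CODES)) < cfg.prop_observed
        for pi, prop in enumerate(PROPERTY_CODES):
            if not observed[pi]:
                continue
            n_articles = int(ephys_rng.integers(lo, hi + 1))
            for _ in range(n_articles):
                article_counter += 1
                article = f"art{article_counter:05d}"
                species = str(ephys_rng.choice(["mouse", "rat", "guinea_pig"], p=[0.7, 0.25, 0.05]))
                prep = str(ephys_rng.choice(["acute_slice", "in_vivo", "culture"], p=[0.9, 0.05, 0.05]))
                electrode = str(ephys_rng.choice(["patch", "sharp"], p=[0.8, 0.2]))
                jxn = str(ephys_rng.choice(["corrected", "not_corrected", "unreported"], p=[0.2, 0.5, 0.3]))
                age = float(ages[i] * np.exp(ephys_rng.normal(0.0, 0.05)))
                if ephys_rng.random() < 0.6:
                    temp = float(ephys_rng.uniform(32, 36))
                else:
                    temp = float(ephys_rng.uniform(21, 25))
                val = float(latent.loc[t, prop])
                for le in lab_by_prop.get(prop, []):
                    if le.covariate == "temp":
                        val += le.magnitude * (temp - REFERENCE_TEMP_C)
                    elif le.covariate == "age":
                        val += le.magnitude * (np.log10(age) - REFERENCE_LOG10_AGE)
                    elif le.covariate == "electrode" and electrode == "sharp":
                        val += le.magnitude
                    elif le.covariate == "jxn" and jxn == "not_corrected":
                        val += le.magnitude
                    elif le.covariate == "species" and species == "rat":
                        val += le.magnitude
                val += float(ephys_rng.normal(0.0, cfg.measurement_noise_sd[prop]))
                offset = None
                if jxn == "corrected" and prop in VOLTAGE_PROPERTIES:
                    # the article subtracted its LJP offset from reported voltages
                    offset = float(ephys_rng.uniform(8, 15))
                    val -= offset
                native = float(from_model_scale(prop, val))
                if prop in LOG10_PROPERTIES and native <= 0:
                    native = np.nextafter(0, 1)
                age_lo = age_hi = age
                if ephys_rng.random() < 0.2:
                    age_lo, age_hi = age * 0.9, age * 1.15
                report_age = ephys_rng.random() >= 0.05
                report_temp = ephys_rng.random() >= 0.05
                records.append(
                    EphysMeasurement(
                        article_id=article,
                        cell_type_label=t,
                        property=prop,
                        value=native,
                        species=species,
                        preparation=prep,
                        electrode=electrode,
                        jxn_status=jxn,
                        jxn_offset_mV=offset,
                        age_lo_days=age_lo if report_age else None,
                        age_hi_days=age_hi if report_age else None,
                        rec_temp_C=temp if report_temp else None,
                    )
                )

    out_truth = GroundTruth(
        planted_effects=list(truth.planted_effects),
        lab_effects=list(truth.lab_effects),
        coexpression_blocks=[list(b) for b in truth.coexpression_blocks],
        null_genes=set(truth.null_genes),
        latent_ephys=latent,
        type_ages=type_ages,
        type_gene_means=pd.DataFrame(means, index=types, columns=genes),
    )
    return expr, records, out_truth


def generate_validation_dataset(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a validation-style single-cell dataset from shared truth.

    Uses the latents realized by :func:`generate_discovery_dataset` (which
    must have been run on the shared ``truth``): ``cfg.n_lines`` cell types
    become transgenic lines; each contributes ``cfg.cells_per_line``
    transcriptomic cells (TPM exponentiated from the latent log2 signal,
    zeros injected at ``cfg.dropout_rate``) and a disjoint set of ephys
    cells whose per-cell values are drawn around the same latent means.

    Returns the single-cell expression matrix (tpm scale, line label in the
    metadata) and a per-cell ephys table with one row per (cell, property).
    """
    if truth.type_gene_means is None or truth.latent_ephys is None:
        raise ValueError(
            "truth has no realized latents; run generate_discovery_dataset first"
        )
    if cfg.cells_per_line < 1:
        raise ValueError("cells_per_line must be >= 1")
    rng = substream(cfg.seed, "validation")
    all_types = list(truth.type_gene_means.index)
    if cfg.n_lines > len(all_types):
        raise ValueError("n_lines exceeds the number of generated cell types")
    lines = sorted(rng.choice(len(all_types), size=cfg.n_lines, replace=False).tolist())
    line_labels = [all_types[i] for i in lines]
    genes = list(truth.type_gene_means.columns)

    sample_ids, labels = [], []
    tpm_blocks = []
    for t in line_labels:
        m = truth.type_gene_means.loc[t].to_numpy()
        cells = m[None, :] + cfg.cell_noise_sd * rng.standard_normal(
            (cfg.cells_per_line, len(genes))
        )
        tpm = np.exp2(cells - cfg.background_level)
        if cfg.dropout_rate > 0:
            tpm[rng.random(tpm.shape) < cfg.dropout_rate] = 0.0
        tpm_blocks.append(tpm)
        for c in range(cfg.cells_per_line):
            sample_ids.append(f"{t}_sc{c + 1}")
            labels.append(t)
    values = pd.DataFrame(np.vstack(tpm_blocks).T, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {"cell_type_label": labels, "platform": "scRNAseq"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = ExpressionMatrix(values=values, scale="tpm", sample_meta=meta)

    rows = []
    for t in line_labels:
        for c in range(cfg.cells_per_line):
            row: dict[str, object] = {
                "cell_id": f"{t}_ephys{c + 1}",
                "cell_type_label": t,
            }
            for prop in PROPERTY_CODES:
                val = float(truth.latent_ephys.loc[t, prop]) + float(
                    rng.normal(0.0, cfg.measurement_noise_sd[prop])
                )
                row[prop] = float(from_model_scale(prop, val))
            rows.append(row)
    ephys_cells = pd.DataFrame(rows).set_index("cell_id")
    return expr, ephys_cells


def save_ground_truth(truth: GroundTruth, directory) -> None:
    """Serialize ground truth next to a generated dataset.

    Writes ``ground_truth.json`` (planted effects, lab effects, blocks,
    null genes) plus, when realized, ``latent_ephys.tsv`` and
    ``type_gene_means.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "planted_effects": [
            {
                "gene": e.gene,
                "property": e.property,
                "direction": "+" if e.direction > 0 else "-",
                "target_abs_spearman": e.target_abs_spearman,
            }
            for e in truth.planted_effects
        ],
        "lab_effects": [
            {"property": le.property, "covariate": le.covariate, "magnitude": le.magnitude}
            for le in truth.lab_effects
        ],
        "coexpression_blocks": [list(b) for b in truth.coexpression_blocks],
        "null_genes": sorted(truth.null_genes),
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(payload, indent=1), encoding="utf-8"
    )
    if truth.latent_ephys is not None:
        truth.latent_ephys.to_csv(directory / "latent_ephys.tsv", sep="\t")
    if truth.type_gene_means is not None:
        truth.type_gene_means.to_csv(directory / "type_gene_means.tsv", sep="\t")
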
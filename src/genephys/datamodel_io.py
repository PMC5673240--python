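"""Shared domain types, delimited-text I/O, and run configuration.

The package analyses paired cell-type-level data: gene expression profiles
(pooled-cell microarray on log2 scale, or single-cell RNA-seq TPM) and
intrinsic electrophysiological ("ephys") properties curated from the
literature.  Everything downstream speaks in terms of the types defined
here:

* :class:`EphysPropertyDef` / :data:`PROPERTY_REGISTRY` -- the closed set of
  11 intrinsic ephys properties and their modeling transforms.
* :class:`ExpressionMatrix` -- feature x sample values plus sample metadata.
* :class:`EphysMeasurement` -- one article-level measurement of one property
  for one cell type, with methodological metadata.
* :class:`PairedCellTypeDataset` -- cell types x (expression, ephys) after
  harmonization; the unit of all screening and modeling.
* :class:`RunConfig` -- the analysis constants (FDR levels, permutation
  counts, elastic-net settings, ...).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("genephys")

__all__ = [
    "EphysPropertyDef",
    "PROPERTY_REGISTRY",
    "PROPERTY_CODES",
    "LOG10_PROPERTIES",
    "VOLTAGE_PROPERTIES",
    "ExpressionMatrix",
    "EphysMeasurement",
    "PairedCellTypeDataset",
    "RunConfig",
    "substream",
    "to_model_scale",
    "from_model_scale",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ephys_table",
    "write_ephys_table",
]


# ---------------------------------------------------------------------------
# Property registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysPropertyDef:
    """Definition of one intrinsic electrophysiological property."""

    name: str
    units: str
    log10_transform: bool
    higher_is: str


#: The closed registry of the 11 intrinsic ephys properties analysed here.
#: Skewed, strictly positive properties are log10-transformed before any
#: cross-study modeling; voltages and SFA are modelled on their native scale.
PROPERTY_REGISTRY: dict[str, EphysPropertyDef] = {
    p.name: p
    for p in [
        EphysPropertyDef("Vrest", "mV", False, "more depolarized resting potential"),
        EphysPropertyDef("Rin", "MOhm", True, "higher input resistance"),
        EphysPropertyDef("Tau", "ms", True, "slower membrane time constant"),
        EphysPropertyDef("Cm", "pF", True, "larger membrane capacitance"),
        EphysPropertyDef("APamp", "mV", False, "taller action potential"),
        EphysPropertyDef("APhw", "ms", True, "wider spike at half height"),
        EphysPropertyDef("APthr", "mV", False, "more depolarized spike threshold"),
        EphysPropertyDef("AHPamp", "mV", False, "deeper afterhyperpolarization"),
        EphysPropertyDef("Rheo", "pA", True, "more current needed to spike"),
        EphysPropertyDef("FRmax", "Hz", True, "faster maximal firing"),
        EphysPropertyDef("SFA", "ratio", False, "less spike-frequency adaptation"),
    ]
}

PROPERTY_CODES: tuple[str, ...] = tuple(PROPERTY_REGISTRY)

LOG10_PROPERTIES: frozenset[str] = frozenset(
    p.name for p in PROPERTY_REGISTRY.values() if p.log10_transform
)

#: Properties expressed as absolute voltages, which a liquid-junction-potential
#: offset shifts additively.  Amplitude-type voltages (APamp, AHPamp) are
#: differences between two voltages and are unaffected by an LJP offset.
VOLTAGE_PROPERTIES: frozenset[str] = frozenset({"Vrest", "APthr"})


def check_property(code: str) -> str:
    if code not in PROPERTY_REGISTRY:
        raise ValueError(
            f"unknown ephys property code {code!r}; registered codes: "
            f"{', '.join(PROPERTY_CODES)}"
        )
    return code


def to_model_scale(prop: str, values):
    """Map native-unit values onto the property's modeling scale.

    Positive-valued, right-skewed properties (Rin, Tau, APhw, Cm, Rheo,
    FRmax) are log10-transformed; the rest pass through unchanged.
    """
    check_property(prop)
    arr = np.asarray(values, dtype=float)
    if prop in LOG10_PROPERTIES:
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise ValueError(f"{prop} requires positive values for log10 transform")
        return np.log10(arr)
    return arr


def from_model_scale(prop: str, values):
    """Inverse of :func:`to_model_scale`."""
    check_property(prop)
    arr = np.asarray(values, dtype=float)
    if prop in LOG10_PROPERTIES:
        return 10.0 ** arr
    return arr


# ---------------------------------------------------------------------------
# Random-stream management
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child generator of a master seed.

    Each (seed, name) pair yields an independent stream, so e.g. adding
    genes to the expression stream does not perturb the ephys draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

EXPRESSION_SCALES = ("log2_intensity", "tpm", "log2_tpm1", "zscore")


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns.  ``sample_meta`` is indexed by sample id and carries at least
    ``cell_type_label``; ``age_days`` and ``platform`` are optional.
    """

    values: pd.DataFrame
    scale: str
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"unknown expression scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing_meta = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta}")
        if "cell_type_label" not in self.sample_meta.columns:
            raise ValueError("sample_meta must contain a cell_type_label column")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "non-finite expression value at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta_for_samples(self) -> pd.DataFrame:
        """Metadata aligned to the matrix's sample order."""
        return self.sample_meta.loc[list(self.values.columns)]


def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a UTF-8 table, auto-detecting tab vs comma from the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["NA", ""], keep_default_na=False)


def _meta_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta" + path.suffix)


def read_expression_matrix(path, scale: str) -> ExpressionMatrix:
    """Read an expression matrix plus its sibling sample-metadata table.

    The matrix file has feature ids in the first column and one column per
    sample; the metadata table (``<stem>.meta<suffix>`` next to it) is keyed
    by ``sample_id``.  Non-numeric or non-finite cells are hard errors.
    """
    path = Path(path)
    raw = _read_delimited(path)
    feature_col = raw.columns[0]
    raw = raw.set_index(feature_col)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids: {dups}")
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
                ) from None
        raise
    if values.isna().to_numpy().any():
        loc = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at feature {values.index[loc[0]]!r}, "
            f"sample {values.columns[loc[1]]!r}"
        )
    meta = _read_delimited(_meta_path(path)).set_index("sample_id")
    meta.index = meta.index.astype(str)
    return ExpressionMatrix(values=values, scale=scale, sample_meta=meta)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix and its sibling metadata table as tab-delimited text."""
    path = Path(path)
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")
    meta = m.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(_meta_path(path), sep="\t")


# ---------------------------------------------------------------------------
# Ephys measurements
# ---------------------------------------------------------------------------

SPECIES_LEVELS = ("mouse", "rat", "guinea_pig", "other")
PREPARATION_LEVELS = ("acute_slice", "in_vivo", "culture", "other")
ELECTRODE_LEVELS = ("patch", "perforated_patch", "sharp", "unreported")
JXN_LEVELS = ("corrected", "not_corrected", "unreported", "post_corrected")


@dataclass
class EphysMeasurement:
    """One article-level measurement of one ephys property for one cell type."""

    article_id: str
    cell_type_label: str
    property: str
    value: float
    species: str = "mouse"
    preparation: str = "acute_slice"
    electrode: str = "patch"
    jxn_status: str = "unreported"
    jxn_offset_mV: float | None = None
    age_lo_days: float | None = None
    age_hi_days: float | None = None
    rec_temp_C: float | None = None

    def __post_init__(self) -> None:
        check_property(self.property)
        for attr, levels in [
            ("species", SPECIES_LEVELS),
            ("preparation", PREPARATION_LEVELS),
            ("electrode", ELECTRODE_LEVELS),
            ("jxn_status", JXN_LEVELS),
        ]:
            val = getattr(self, attr).lower()
            if val not in levels:
                raise ValueError(f"unknown {attr} level {val!r} (allowed: {levels})")
            object.__setattr__(self, attr, val)
        if (
            self.age_lo_days is not None
            and self.age_hi_days is not None
            and self.age_lo_days > self.age_hi_days
        ):
            raise ValueError(
                f"age_lo_days {self.age_lo_days} > age_hi_days {self.age_hi_days}"
            )


_EPHYS_COLUMNS = [
    "article_id",
    "cell_type_label",
    "property",
    "value",
    "species",
    "preparation",
    "electrode",
    "jxn_status",
    "jxn_offset_mV",
    "age_days",
    "rec_temp_C",
]


def _parse_age(cell) -> tuple[float | None, float | None]:
    """Parse an age cell: empty -> missing, "14-20" -> (14, 20), "16" -> (16, 16)."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None, None
    text = str(cell).strip()
    if not text or text.upper() == "NA":
        return None, None
    # ages are non-negative, so any interior '-' marks a "lo-hi" range
    if not text.startswith("-") and "-" in text:
        lo_s, hi_s = text.split("-", 1)
        return float(lo_s), float(hi_s)
    val = float(text)
    return val, val


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text or text.upper() == "NA":
        return None
    return float(text)


def read_ephys_table(path) -> list[EphysMeasurement]:
    """Read a curated ephys measurement table (one row per measurement).

    Enum columns are parsed case-insensitively; empty cells and "NA" mean
    missing; an ``age_days`` cell of the form "lo-hi" is split into the two
    age bounds.  Unknown property codes and non-numeric values are hard
    errors.
    """
    raw = _read_delimited(Path(path))
    records: list[EphysMeasurement] = []
    for i, row in raw.iterrows():
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric value {row['value']!r} in row {i}"
            ) from None
        age_lo, age_hi = _parse_age(row.get("age_days"))
        records.append(
            EphysMeasurement(
                article_id=str(row["article_id"]),
                cell_type_label=str(row["cell_type_label"]),
                property=check_property(str(row["property"])),
                value=value,
                species=str(row.get("species", "mouse") or "mouse"),
                preparation=str(row.get("preparation", "acute_slice") or "acute_slice"),
                electrode=str(row.get("electrode", "patch") or "patch"),
                jxn_status=str(row.get("jxn_status", "unreported") or "unreported"),
                jxn_offset_mV=_opt_float(row.get("jxn_offset_mV")),
                age_lo_days=age_lo,
                age_hi_days=age_hi,
                rec_temp_C=_opt_float(row.get("rec_temp_C")),
            )
        )
    return records


def write_ephys_table(records: Sequence[EphysMeasurement], path) -> None:
    rows = []
    for r in records:
        if r.age_lo_days is None:
            age = ""
        elif r.age_hi_days is not None and r.age_hi_days != r.age_lo_days:
            age = f"{r.age_lo_days:g}-{r.age_hi_days:g}"
        else:
            age = f"{r.age_lo_days:g}"
        rows.append(
            {
                "article_id": r.article_id,
                "cell_type_label": r.cell_type_label,
                "property": r.property,
                "value": repr(r.value),
                "species": r.species,
                "preparation": r.preparation,
                "electrode": r.electrode,
                "jxn_status": r.jxn_status,
                "jxn_offset_mV": "" if r.jxn_offset_mV is None else repr(r.jxn_offset_mV),
                "age_days": age,
                "rec_temp_C": "" if r.rec_temp_C is None else repr(r.rec_temp_C),
            }
        )
    pd.DataFrame(rows, columns=_EPHYS_COLUMNS).to_csv(path, sep="\t", index=False)


def ephys_records_to_frame(records: Iterable[EphysMeasurement]) -> pd.DataFrame:
    """Convenience: records as a DataFrame (one row per measurement)."""
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# Paired dataset
# ---------------------------------------------------------------------------

@dataclass
class PairedCellTypeDataset:
    """Cell types x (gene expression vector, per-property ephys values).

    ``expression`` is complete (cell_type x gene); ``ephys`` (cell_type x
    property) may contain NaN where a property was never measured for a
    type.  ``provenance`` keeps free-text notes per cell type (e.g. which
    labels were merged, which were dropped at age matching).
    """

    expression: pd.DataFrame
    ephys: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.ephys.index):
            raise ValueError("expression and ephys must share the same cell-type index")
        if self.expression.isna().to_numpy().any():
            raise ValueError("expression side of a paired dataset must be complete")
        unknown = [p for p in self.ephys.columns if p not in PROPERTY_REGISTRY]
        if unknown:
            raise ValueError(f"unregistered ephys properties: {unknown}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    def n_complete(self, prop: str) -> int:
        """Number of cell types with a non-missing value for ``prop``."""
        check_property(prop)
        if prop not in self.ephys.columns:
            return 0
        return int(self.ephys[prop].notna().sum())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis constants shared across the pipeline.

    Defaults follow the published analysis: BH FDR reported at 0.01/0.05/0.1,
    cross-dataset consistency requires |r_s| > 0.3 with matching sign, 1000
    label-shuffle permutations, 100 bootstrap resamples, elastic-net mixing
    0.99 over a 100-value penalty path, >= 10 cells per cre-line, and +/- 2.5
    day age matching.
    """

    seed: int = 0
    bh_alpha_levels: tuple[float, ...] = (0.01, 0.05, 0.1)
    consistency_abs_r: float = 0.3
    n_permutations: int = 1000
    n_bootstrap: int = 100
    enet_alpha: float = 0.99
    enet_nlambda: int = 100
    min_cells_per_line: int = 10
    age_match_tolerance_days: float = 2.5
    min_celltypes_per_property: int = 5
    exclusions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.consistency_abs_r < 1):
            raise ValueError("consistency_abs_r must be in (0, 1)")
        if not (0 < self.enet_alpha <= 1):
            raise ValueError("enet_alpha must be in (0, 1]")
        for attr in (
            "n_permutations",
            "n_bootstrap",
            "enet_nlambda",
            "min_cells_per_line",
            "min_celltypes_per_property",
        ):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be a positive count")
        if self.age_match_tolerance_days < 0:
            raise ValueError("age_match_tolerance_days must be non-negative")
        self.bh_alpha_levels = tuple(sorted(float(a) for a in self.bh_alpha_levels))
        self.exclusions = tuple((str(t), check_property(p)) for t, p in self.exclusions)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML or JSON config file."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if "exclusions" in data:
            data["exclusions"] = tuple(tuple(x) for x in data["exclusions"])
        if "bh_alpha_levels" in data:
            data["bh_alpha_levels"] = tuple(data["bh_alpha_levels"])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["bh_alpha_levels"] = list(self.bh_alpha_levels)
        data["exclusions"] = [list(x) for x in self.exclusions]
        Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")
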
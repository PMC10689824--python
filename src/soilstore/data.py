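"""Tidy data model for the soil fertility gradient, plus derived indices.

One row per field replicate (or per site mean), snake_case headers, UTF-8 CSV
with "." decimals and empty string for missing optional values.  The packaged
fixture ``table1_site_means.csv`` carries the published site means for the
eight West Head sites, including the printed per-SOC storage columns (stored
verbatim because they are means of replicate-level ratios, not ratios of the
printed means).

Unit conventions
----------------
* ``total_organic_c`` is a fraction of dry soil mass (0.0428 = 4.28 %).
* soluble C, N, P pools, MBC/MBP and storage compounds are ug (C/N/P) per g
  dry soil; PLFA pools are nmol per g dry soil; enzyme activities are
  ug PNP g soil-1 h-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import EmptyDataError, SchemaError, ValidationError

SOIL_TYPES = ("basalt", "shale", "ironstone", "sandstone")
FERTILE_TYPES = frozenset({"basalt", "shale"})

#: chloroform fumigation-extraction flush-to-biomass conversion
MBC_CORRECTION_FACTOR = 2.64

#: default atomic masses for mass<->molar C:P conversion (integer convention)
ATOMIC_MASS_C = 12.0
ATOMIC_MASS_P = 31.0

MANDATORY_COLUMNS = [
    "sample_id",
    "site_id",
    "soil_type",
    "fertility_class",
    "total_organic_c",
    "soluble_organic_c",
    "total_n",
    "total_p",
    "mehlich_po4",
    "mbc",
    "mbp",
    "plfa_total",
    "plfa_bacterial",
    "plfa_fungal",
    "nlfa_c",
    "phb_c",
    "phosphomonoesterase",
    "phosphodiesterase",
    "glucosidase",
]

OPTIONAL_COLUMNS = ["plfa_gram_pos", "plfa_gram_neg", "trehalose_c"]

_NONNEG_FIELDS = [
    "soluble_organic_c",
    "total_n",
    "total_p",
    "mehlich_po4",
    "mbc",
    "mbp",
    "plfa_total",
    "plfa_bacterial",
    "plfa_fungal",
    "plfa_gram_pos",
    "plfa_gram_neg",
    "nlfa_c",
    "phb_c",
    "trehalose_c",
    "phosphomonoesterase",
    "phosphodiesterase",
    "glucosidase",
]


@dataclass
class SoilSample:
    """Chemistry, biomass, storage and enzyme measurements for one sample."""

    sample_id: str
    site_id: str
    soil_type: str
    fertility_class: str
    total_organic_c: float
    soluble_organic_c: float
    total_n: float
    total_p: float
    mehlich_po4: float
    mbc: float
    mbp: float
    plfa_total: float
    plfa_bacterial: float
    plfa_fungal: float
    nlfa_c: float
    phb_c: float
    phosphomonoesterase: float
    phosphodiesterase: float
    glucosidase: float
    plfa_gram_pos: Optional[float] = None
    plfa_gram_neg: Optional[float] = None
    trehalose_c: Optional[float] = None


@dataclass
class GradientDataset:
    """An ordered collection of soil samples at replicate or site-mean level.

    ``frame`` keeps any extra columns present in the source CSV (the fixture
    carries the printed per-SOC and C:P ratio columns, for example).
    """

    frame: pd.DataFrame
    level: str  # "replicate" | "site_mean"

    def __post_init__(self) -> None:
        if self.level not in ("replicate", "site_mean"):
            raise ValidationError(f"unknown dataset level {self.level!r}")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[SoilSample]:
        return iter(self.samples())

    def samples(self) -> list[SoilSample]:
        names = {f.name for f in dc_fields(SoilSample)}
        out = []
        for _, row in self.frame.iterrows():
            kwargs = {k: row[k] for k in names if k in row.index}
            for opt in OPTIONAL_COLUMNS:
                if opt in kwargs and pd.isna(kwargs[opt]):
                    kwargs[opt] = None
            out.append(SoilSample(**kwargs))
        return out


@dataclass
class PlfaProfile:
    """Per-sample PLFA marker amounts (nmol g soil-1) with taxon assignments."""

    sample_id: str
    marker_amounts: dict[str, float]
    taxon_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, amount in self.marker_amounts.items():
            if amount < 0:
                raise ValidationError(
                    f"marker {marker!r} in sample {self.sample_id!r} is negative"
                )
        for marker in self.marker_amounts:
            self.taxon_assignment.setdefault(marker, "unassigned")


def _validate_rows(df: pd.DataFrame) -> None:
    """Raise ValidationError naming field and 0-based row for any violation."""
    problems: list[str] = []
    for i, row in df.iterrows():
        for col in _NONNEG_FIELDS:
            if col in df.columns and pd.notna(row[col]) and row[col] < 0:
                problems.append(f"row {i}: {col} = {row[col]} is negative")
        soc = row["total_organic_c"]
        if pd.isna(soc) or not (0 < soc < 1):
            problems.append(
                f"row {i}: total_organic_c = {soc} outside (0, 1) fraction range"
            )
        if row["soil_type"] not in SOIL_TYPES:
            problems.append(f"row {i}: unknown soil_type {row['soil_type']!r}")
        else:
            expected = "fertile" if row["soil_type"] in FERTILE_TYPES else "infertile"
            if row["fertility_class"] != expected:
                problems.append(
                    f"row {i}: fertility_class {row['fertility_class']!r} "
                    f"inconsistent with soil_type {row['soil_type']!r}"
                )
        if (
            pd.notna(row["plfa_bacterial"])
            and pd.notna(row["plfa_fungal"])
            and pd.notna(row["plfa_total"])
            and row["plfa_bacterial"] + row["plfa_fungal"] > row["plfa_total"] * (1 + 1e-9)
        ):
            problems.append(
                f"row {i}: plfa_bacterial + plfa_fungal exceeds plfa_total"
            )
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        problems.append(f"duplicate sample_ids: {dups}")
    if problems:
        raise ValidationError("; ".join(problems))


def load_gradient_csv(path: str | Path, level: str = "replicate") -> GradientDataset:
    """Read and validate a gradient sample table.

    An empty table (header only) is a valid dataset of zero samples.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for opt in OPTIONAL_COLUMNS:
        if opt not in df.columns:
            df[opt] = np.nan
    if len(df):
        _validate_rows(df)
    return GradientDataset(frame=df, level=level)


def write_gradient_csv(dataset: GradientDataset, path: str | Path) -> None:
    """Write a dataset back to CSV (full precision) with a sidecar JSON."""
    path = Path(path)
    dataset.frame.to_csv(path, index=False)
    sidecar = {"level": dataset.level, "n_records": len(dataset)}
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def load_table1_fixture() -> GradientDataset:
    """The packaged site-mean fixture: 8 records, 4 soil types."""
    with resources.as_file(
        resources.files("soilstore.fixtures") / "table1_site_means.csv"
    ) as p:
        ds = load_gradient_csv(p, level="site_mean")
    if len(ds) != 8:
        raise ValidationError("site-mean fixture must have exactly 8 records")
    return ds


def mbc_from_flush(flush_c: float) -> float:
    """Microbial biomass C from the fumigation C flush (factor 2.64)."""
    if flush_c < 0:
        raise ValidationError(f"flush_c = {flush_c} must be >= 0")
    return flush_c * MBC_CORRECTION_FACTOR


def per_soc_normalise(storage_c: float, total_organic_c: float) -> float:
    """Storage content per g of soil organic C (ug C g SOC-1)."""
    if total_organic_c <= 0:
        raise ValidationError(
            f"total_organic_c = {total_organic_c} must be positive"
        )
    return storage_c / total_organic_c


def cp_mass_to_molar(
    cp_mass: float, mass_c: float = ATOMIC_MASS_C, mass_p: float = ATOMIC_MASS_P
) -> float:
    """Convert a mass-basis C:P ratio to a molar basis (default 31/12)."""
    if cp_mass < 0:
        raise ValidationError(f"cp_mass = {cp_mass} must be >= 0")
    return cp_mass * (mass_p / mass_c)


def fungal_bacterial_ratio(sample: SoilSample) -> float:
    """Fungal:bacterial PLFA ratio (molar; both pools are nmol g soil-1)."""
    if sample.plfa_bacterial <= 0:
        raise ValidationError(
            f"sample {sample.sample_id!r}: bacterial PLFA must be positive"
        )
    return sample.plfa_fungal / sample.plfa_bacterial


def summarise_range(
    dataset: GradientDataset, field_name: str, statistic: str
) -> tuple[float, str]:
    """(statistic over non-missing values, sample_id attaining it).

    For ``mean`` the returned id is the sample closest to the mean (first in
    input order on ties); for min/max, ties break to the first occurrence.
    """
    if field_name not in dataset.frame.columns:
        raise SchemaError(f"no such field {field_name!r}")
    col = pd.to_numeric(dataset.frame[field_name], errors="coerce")
    ok = col.notna()
    if not ok.any():
        raise EmptyDataError(f"field {field_name!r} has no non-missing values")
    vals = col[ok]
    ids = dataset.frame.loc[ok, "sample_id"]
    if statistic == "min":
        pos = int(np.argmin(vals.to_numpy()))
        return float(vals.iloc[pos]), str(ids.iloc[pos])
    if statistic == "max":
        pos = int(np.argmax(vals.to_numpy()))
        return float(vals.iloc[pos]), str(ids.iloc[pos])
    if statistic == "mean":
        m = float(vals.mean())
        pos = int(np.argmin(np.abs(vals.to_numpy() - m)))
        return m, str(ids.iloc[pos])
    raise ValueError(f"unknown statistic {statistic!r}")


def storage_fraction_of_mbc(sample: SoilSample) -> float:
    """Summed storage C (NLFA + PHB + trehalose) as a fraction of MBC."""
    if sample.mbc <= 0:
        raise ValidationError(
            f"sample {sample.sample_id!r}: mbc must be positive"
        )
    trehalose = sample.trehalose_c if sample.trehalose_c is not None else 0.0
    return (sample.nlfa_c + sample.phb_c + trehalose) / sample.mbc


def mean_storage_fraction(dataset: GradientDataset) -> float:
    """Mean of per-sample storage fractions across a dataset."""
    fracs = [storage_fraction_of_mbc(s) for s in dataset.samples()]
    return float(np.mean(fracs))


def fungal_bacterial_contrast(dataset: GradientDataset) -> float:
    """Infertile-to-fertile fold difference in mean fungal:bacterial ratio."""
    by_class: dict[str, list[float]] = {"fertile": [], "infertile": []}
    for s in dataset.samples():
        by_class[s.fertility_class].append(fungal_bacterial_ratio(s))
    for k, v in by_class.items():
        if not v:
            raise EmptyDataError(f"no samples in fertility class {k!r}")
    return float(np.mean(by_class["infertile"]) / np.mean(by_class["fertile"]))
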
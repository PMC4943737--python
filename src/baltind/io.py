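"""Readers, writers and validation for zooplankton monitoring tables.

Three plain-text (CSV) inputs drive the pipeline:

* a long-format **sample table** — one row per dataset x station x date x
  taxon (x life stage) observation, carrying abundance (ind m-3) and/or
  wet-weight biomass (mg WW m-3) plus, optionally, mean individual wet
  weight (ug ind-1);
* a **taxon trait registry** assigning each taxon to the functional
  classes the indicators need (copepod / calanoid, herbivorous vs
  predatory cladoceran, microphagous feeder, ...);
* optional **reference-period definitions** — year windows per dataset
  used as the controlling baseline of the control charts.

All tables are held as :class:`pandas.DataFrame` with canonical column
names; the record/trait/window dataclasses below document the row
contracts and back the validation helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "MajorGroup",
    "RefConKind",
    "SampleRecord",
    "TaxonTraits",
    "RefConWindow",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "SAMPLE_COLUMNS",
    "SUMMER_MONTHS",
    "BIOMASS_RTOL",
    "read_samples",
    "write_samples",
    "validate_samples",
    "read_taxon_traits",
    "validate_traits",
    "read_refcon",
    "validate_dataset",
]

#: relative tolerance for the biomass = abundance x ind_mass x 1e-3 identity
BIOMASS_RTOL = 1e-6

#: canonical sample-table columns
SAMPLE_COLUMNS = (
    "dataset",
    "station",
    "date",
    "taxon",
    "stage",
    "abundance",
    "ind_mass",
    "biomass",
)

#: default summer window (calendar months) used throughout the assessment
SUMMER_MONTHS = (6, 7, 8, 9)


class SchemaError(ValueError):
    """A required column is missing or not mappable."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


class Stage(str, Enum):
    adult = "adult"
    copepodite = "copepodite"
    nauplius = "nauplius"
    unspecified = "unspecified"


class MajorGroup(str, Enum):
    copepod = "copepod"
    cladoceran = "cladoceran"
    rotifer = "rotifer"
    tintinnid = "tintinnid"
    appendicularian = "appendicularian"
    ctenophore = "ctenophore"
    harpacticoid = "harpacticoid"
    other = "other"


class RefConKind(str, Enum):
    refcon_chl = "refcon_chl"
    refcon_fish = "refcon_fish"
    entire = "entire"


@dataclass(frozen=True)
class SampleRecord:
    """One taxon x station x date observation.

    Units: abundance ind m-3 (>= 0), individual mass ug WW ind-1 (> 0),
    biomass mg WW m-3 (>= 0).  When abundance and individual mass are both
    present, biomass = abundance x ind_mass x 1e-3 within
    :data:`BIOMASS_RTOL`; at least one of abundance / biomass must be
    present.
    """

    dataset: str
    station: str
    date: pd.Timestamp
    taxon: str
    stage: Stage = Stage.unspecified
    abundance: float | None = None
    ind_mass: float | None = None
    biomass: float | None = None


@dataclass(frozen=True)
class TaxonTraits:
    """Functional classification of one taxon.

    Invariants: calanoids are copepods; predatory cladocerans are
    cladocerans and never microphagous.
    """

    taxon: str
    major_group: MajorGroup
    is_calanoid: bool = False
    is_predatory_cladoceran: bool = False
    is_microphagous: bool = False

    def __post_init__(self) -> None:
        if self.is_calanoid and self.major_group is not MajorGroup.copepod:
            raise ValidationError(
                f"{self.taxon}: is_calanoid requires major_group=copepod"
            )
        if self.is_predatory_cladoceran:
            if self.major_group is not MajorGroup.cladoceran:
                raise ValidationError(
                    f"{self.taxon}: is_predatory_cladoceran requires "
                    "major_group=cladoceran"
                )
            if self.is_microphagous:
                raise ValidationError(
                    f"{self.taxon}: predatory cladocerans are never microphagous"
                )


@dataclass(frozen=True)
class RefConWindow:
    """A reference-condition year window for one dataset."""

    dataset: str
    kind: RefConKind
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValidationError(
                f"{self.dataset}: start_year {self.start_year} > "
                f"end_year {self.end_year}"
            )

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass
class ValidationReport:
    """Report-only cross-check of a sample table against a trait registry."""

    unmapped_taxa: list[str] = field(default_factory=list)
    years_without_summer: dict[str, list[int]] = field(default_factory=dict)
    stations_per_year: pd.DataFrame | None = None
    issues: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.issues


# ---------------------------------------------------------------------------
# unit handling

_UNIT_FACTORS: dict[str, dict[str, float]] = {
    # to ind m-3
    "abundance": {"ind_m3": 1.0, "ind_L": 1000.0, "ind_10m3": 0.1},
    # to ug ind-1
    "ind_mass": {"ug": 1.0, "mg": 1000.0},
    # to mg WW m-3
    "biomass": {"mg_m3": 1.0, "ug_L": 1.0, "g_m3": 1000.0, "ug_m3": 1e-3},
}


def _unit_factor(column: str, unit: str) -> float:
    try:
        return _UNIT_FACTORS[column][unit]
    except KeyError:
        raise SchemaError(f"unknown unit {unit!r} for column {column!r}") from None


# ---------------------------------------------------------------------------
# sample table

def read_samples(
    path,
    schema: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format sample table.

    Parameters
    ----------
    path
        CSV file with columns ``dataset,station,date,taxon,stage,
        abundance,ind_mass,biomass`` (empty cell = missing).  ``stage``
        and the numeric columns are optional, but each row needs at least
        one of abundance / biomass.
    schema
        Optional mapping canonical name -> column name in the file, for
        files using other headers.
    units
        Optional per-file unit declarations, e.g. ``{"abundance":
        "ind_L"}``; values are converted to the canonical units
        (ind m-3, ug, mg m-3) on ingest.

    Returns
    -------
    DataFrame with canonical columns, validated (see
    :func:`validate_samples`); biomass is derived from abundance x
    individual mass where absent.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("read_samples: %s is empty", path)
        return pd.DataFrame(columns=list(SAMPLE_COLUMNS))
    if raw.empty:
        log.warning("read_samples: %s is empty", path)
        return pd.DataFrame(columns=list(SAMPLE_COLUMNS))

    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)

    for col in ("dataset", "station", "date", "taxon"):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "abundance" not in raw.columns and "biomass" not in raw.columns:
        raise SchemaError(
            f"need at least one of 'abundance'/'biomass' columns in {path}"
        )
    for col in ("stage", "abundance", "ind_mass", "biomass"):
        if col not in raw.columns:
            raw[col] = np.nan

    df = raw.loc[:, list(SAMPLE_COLUMNS)].copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["stage"] = df["stage"].fillna(Stage.unspecified.value)
    bad_stage = ~df["stage"].isin([s.value for s in Stage])
    if bad_stage.any():
        raise ValidationError(
            f"unknown stage values: {sorted(df.loc[bad_stage, 'stage'].unique())}"
        )
    for col in ("abundance", "ind_mass", "biomass"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if units and col in units:
            df[col] = df[col] * _unit_factor(col, units[col])

    df = validate_samples(df)
    log.info("read_samples: %d rows from %s", len(df), path)
    return df


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the sample-record invariants on a canonical table.

    Negative abundance/biomass or non-positive individual mass raise a
    :class:`ValidationError` naming the offending row.  Biomass is derived
    (abundance x ind_mass x 1e-3) where missing; when a reported biomass
    disagrees with the derived one beyond :data:`BIOMASS_RTOL` the
    reported column wins and a warning is logged (monitoring files often
    carry lab-computed biomass).
    """
    df = df.copy()
    for col, minimum, strict in (
        ("abundance", 0.0, False),
        ("biomass", 0.0, False),
        ("ind_mass", 0.0, True),
    ):
        vals = df[col]
        bad = (vals <= minimum) if strict else (vals < minimum)
        bad &= vals.notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"invalid {col} at row {idx}: {vals.iloc[idx]!r}"
            )

    neither = df["abundance"].isna() & df["biomass"].isna()
    if neither.any():
        idx = int(np.flatnonzero(neither.to_numpy())[0])
        raise ValidationError(
            f"row {idx}: at least one of abundance/biomass required"
        )

    derived = df["abundance"] * df["ind_mass"] * 1e-3
    both = df["biomass"].notna() & derived.notna()
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.maximum(np.abs(df.loc[both, "biomass"]), np.abs(derived[both]))
        mismatch = np.abs(df.loc[both, "biomass"] - derived[both]) > (
            BIOMASS_RTOL * scale
        )
    if mismatch.any():
        n = int(mismatch.sum())
        log.warning(
            "validate_samples: %d rows with biomass inconsistent with "
            "abundance x ind_mass; reported biomass kept",
            n,
        )
    fill = df["biomass"].isna() & derived.notna()
    df.loc[fill, "biomass"] = derived[fill]
    # derive abundance where only biomass + individual mass are given
    fill_a = df["abundance"].isna() & df["biomass"].notna() & df["ind_mass"].notna()
    df.loc[fill_a, "abundance"] = (
        df.loc[fill_a, "biomass"] / df.loc[fill_a, "ind_mass"] * 1e3
    )
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a canonical sample table to CSV (ISO dates, full precision)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trait registry

def read_taxon_traits(path) -> pd.DataFrame:
    """Read the taxon trait registry.

    CSV columns: ``taxon,major_group,is_calanoid,is_predatory_cladoceran,
    is_microphagous``.  Returns a DataFrame indexed by taxon.  Duplicate
    taxa, unknown groups and trait-invariant violations raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    for col in ("taxon", "major_group"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    for col in ("is_calanoid", "is_predatory_cladoceran", "is_microphagous"):
        if col not in df.columns:
            df[col] = False
        else:
            df[col] = (
                df[col]
                .map(
                    {
                        True: True,
                        False: False,
                        "True": True,
                        "False": False,
                        "true": True,
                        "false": False,
                        1: True,
                        0: False,
                        "1": True,
                        "0": False,
                    }
                )
                .astype("boolean")
                .fillna(False)
                .astype(bool)
            )
    return validate_traits(df.set_index("taxon"))


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait registry (indexed by taxon)."""
    if traits.index.duplicated().any():
        dups = sorted(traits.index[traits.index.duplicated()].unique())
        raise ValidationError(f"duplicate taxa in trait registry: {dups}")
    valid_groups = {g.value for g in MajorGroup}
    bad = ~traits["major_group"].isin(valid_groups)
    if bad.any():
        raise ValidationError(
            f"unknown major_group values: {sorted(traits.loc[bad, 'major_group'].unique())}"
        )
    # re-run the dataclass invariants row-wise (tables are small)
    for taxon, row in traits.iterrows():
        TaxonTraits(
            taxon=str(taxon),
            major_group=MajorGroup(row["major_group"]),
            is_calanoid=bool(row["is_calanoid"]),
            is_predatory_cladoceran=bool(row["is_predatory_cladoceran"]),
            is_microphagous=bool(row["is_microphagous"]),
        )
    return traits


# ---------------------------------------------------------------------------
# reference windows

def read_refcon(path) -> list[RefConWindow]:
    """Read reference-period definitions (``dataset,kind,start_year,end_year``)."""
    df = pd.read_csv(path)
    for col in ("dataset", "kind", "start_year", "end_year"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    return [
        RefConWindow(
            dataset=str(r.dataset),
            kind=RefConKind(r.kind),
            start_year=int(r.start_year),
            end_year=int(r.end_year),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# cross-validation report

def validate_dataset(
    samples: pd.DataFrame,
    traits: pd.DataFrame,
    months: Sequence[int] = SUMMER_MONTHS,
) -> ValidationReport:
    """Cross-check samples against the trait registry (report-only).

    Lists taxa missing from the registry, years without any sample in the
    summer window, and the station count per dataset x year.  Running it
    twice on the same inputs yields identical reports.
    """
    report = ValidationReport()
    if samples.empty:
        return report

    unmapped = sorted(set(samples["taxon"]) - set(traits.index))
    report.unmapped_taxa = unmapped
    report.issues += [f"unmapped taxon: {t}" for t in unmapped]

    dates = pd.to_datetime(samples["date"])
    years = dates.dt.year
    in_summer = dates.dt.month.isin(list(months))
    for ds, grp_idx in samples.groupby("dataset").groups.items():
        ds_years = years.loc[grp_idx]
        summer_years = set(ds_years[in_summer.loc[grp_idx]])
        missing = sorted(set(ds_years) - summer_years)
        if missing:
            report.years_without_summer[str(ds)] = missing
            report.issues += [
                f"{ds}: no summer coverage in {y}" for y in missing
            ]

    per_year = (
        samples.assign(year=years)
        .groupby(["dataset", "year"])["station"]
        .nunique()
        .rename("n_stations")
        .reset_index()
    )
    report.stations_per_year = per_year
    return report
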
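"""Synthetic multi-decadal zooplankton community datasets.

Real Baltic monitoring series are multi-decadal summer records with
group-structured biomass, strongly right-skewed sampling noise,
monotonic trends, step-like regime shifts and missing years.  The
generator reproduces exactly that statistical structure — it makes no
attempt at mechanistic plankton dynamics — so every pipeline stage
(transformation, imputation, control charts, breakpoints, logistic
models) can be exercised against known ground truth.

Each year x month x station x group observation draws biomass from a
mean-preserving lognormal around the trend- and shift-adjusted group
mean, multiplied by a fixed per-station lognormal factor; abundance
follows exactly from the (fixed) individual mass, so the generated
records satisfy the biomass = abundance x mass x 1e-3 identity by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MajorGroup, RefConKind, RefConWindow, Stage

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "GroundTruth",
    "DEFAULT_GROUPS",
    "default_traits",
    "generate_dataset",
    "generate_null_zscores",
    "make_refcon_truth",
    "composite_shift",
]


@dataclass(frozen=True)
class GroupSpec:
    """Sampling model for one functional group.

    biomass_mean
        Summer mean wet-weight biomass density, mg WW m-3.
    ind_mass
        Individual wet weight, ug; held fixed so derived abundance is
        exactly consistent with biomass.
    noise_cv
        Lognormal coefficient of variation of a single observation.
    trend
        Multiplicative drift per year (0.01 = +1 %/yr).
    shift_factor
        Multiplier applied from the configured shift year onward.
    """

    taxon: str
    major_group: str
    biomass_mean: float
    ind_mass: float
    noise_cv: float = 0.35
    trend: float = 0.0
    shift_factor: float = 1.0
    is_calanoid: bool = False
    is_predatory_cladoceran: bool = False
    is_microphagous: bool = False

    def __post_init__(self) -> None:
        if self.biomass_mean <= 0 or self.ind_mass <= 0:
            raise ValueError(f"{self.taxon}: means must be > 0")
        if self.noise_cv < 0:
            raise ValueError(f"{self.taxon}: noise_cv must be >= 0")


#: Baltic-plausible summer community (biomass mg WW m-3, individual mass ug)
DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "calanoid": GroupSpec(
        "Acartia spp.", MajorGroup.copepod.value, 60.0, 8.0, is_calanoid=True
    ),
    "copepod_other": GroupSpec("Cyclopoida", MajorGroup.copepod.value, 15.0, 4.0),
    "herb_cladoceran": GroupSpec(
        "Bosmina maritima", MajorGroup.cladoceran.value, 25.0, 10.0,
        is_microphagous=True,
    ),
    "pred_cladoceran": GroupSpec(
        "Cercopagis pengoi", MajorGroup.cladoceran.value, 3.0, 150.0,
        is_predatory_cladoceran=True,
    ),
    "rotifer": GroupSpec(
        "Synchaeta spp.", MajorGroup.rotifer.value, 8.0, 0.2, is_microphagous=True
    ),
    "appendicularian": GroupSpec(
        "Fritillaria borealis", MajorGroup.appendicularian.value, 5.0, 5.0,
        is_microphagous=True,
    ),
}

#: regime-shift preset: copepods down, microphagous groups up — displaces
#: the main indicators by roughly two interannual SDs under the default
#: noise and sampling effort
COMPOSITE_SHIFT = {
    "calanoid": 0.85,
    "copepod_other": 0.85,
    "herb_cladoceran": 1.2,
    "rotifer": 1.25,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    dataset: str = "SYN"
    n_years: int = 35
    start_year: int = 1980
    months: tuple[int, ...] = (6, 7, 8, 9)
    samples_per_month: int = 1
    n_stations: int = 2
    station_cv: float = 0.2
    missing_year_prob: float = 0.0
    shift_year: int | None = None  # calendar year of the step change
    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_year_prob < 0.3:
            raise ValueError("missing_year_prob must be in [0, 0.3)")
        if self.n_years < 1 or self.n_stations < 1 or self.samples_per_month < 1:
            raise ValueError("n_years, n_stations, samples_per_month must be >= 1")
        if self.shift_year is not None and not (
            self.start_year < self.shift_year < self.start_year + self.n_years
        ):
            raise ValueError("shift_year must fall inside the series")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)


def composite_shift(config: GeneratorConfig, shift_year: int) -> GeneratorConfig:
    """Config with the composite regime-shift preset applied at ``shift_year``."""
    groups = {
        name: replace(spec, shift_factor=COMPOSITE_SHIFT.get(name, 1.0))
        for name, spec in config.groups.items()
    }
    return replace(config, shift_year=shift_year, groups=groups)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for end-to-end recovery tests."""

    config: GeneratorConfig
    shift_year: int | None
    trend_direction: dict[str, str]  # group -> up/down/none
    missing_years: tuple[int, ...]
    station_factors: dict[str, float]


def default_traits(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Trait registry matching the generator's taxa."""
    groups = (config or GeneratorConfig()).groups
    rows = [
        {
            "taxon": g.taxon,
            "major_group": g.major_group,
            "is_calanoid": g.is_calanoid,
            "is_predatory_cladoceran": g.is_predatory_cladoceran,
            "is_microphagous": g.is_microphagous,
        }
        for g in groups.values()
    ]
    return pd.DataFrame(rows).set_index("taxon")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given CV."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def generate_dataset(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic monitoring dataset.

    Returns the canonical long-format sample table (see
    :mod:`baltind.io`) and the ground truth (shift year, trend signs,
    missing years, station factors).  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    stations = [f"ST{i+1}" for i in range(config.n_stations)]
    station_factor = dict(
        zip(stations, _lognormal_factor(rng, config.station_cv, config.n_stations))
    )
    missing = tuple(
        y
        for y in config.years
        if rng.random() < config.missing_year_prob
    )

    rows = []
    for year in config.years:
        if year in missing:
            continue
        t = year - config.start_year
        for month in config.months:
            for si in range(config.samples_per_month):
                day = min(5 + 10 * si, 28)
                date = f"{year:04d}-{month:02d}-{day:02d}"
                for st in stations:
                    for name, g in config.groups.items():
                        mean = g.biomass_mean * (1.0 + g.trend) ** t
                        if config.shift_year is not None and year >= config.shift_year:
                            mean *= g.shift_factor
                        biomass = (
                            mean
                            * station_factor[st]
                            * _lognormal_factor(rng, g.noise_cv, None)
                        )
                        abundance = biomass * 1e3 / g.ind_mass
                        rows.append(
                            (
                                config.dataset,
                                st,
                                date,
                                g.taxon,
                                Stage.unspecified.value,
                                abundance,
                                g.ind_mass,
                                biomass,
                            )
                        )
    samples = pd.DataFrame(
        rows,
        columns=[
            "dataset",
            "station",
            "date",
            "taxon",
            "stage",
            "abundance",
            "ind_mass",
            "biomass",
        ],
    )
    samples["date"] = pd.to_datetime(samples["date"])
    truth = GroundTruth(
        config=config,
        shift_year=config.shift_year,
        trend_direction={
            name: ("up" if g.trend > 0 else "down" if g.trend < 0 else "none")
            for name, g in config.groups.items()
        },
        missing_years=missing,
        station_factors=station_factor,
    )
    return samples, truth


def generate_null_zscores(
    n_years: int, n_series: int, seed: int | None = None
) -> pd.DataFrame:
    """iid standard-normal z matrices for chart calibration experiments."""
    if n_years < 5:
        raise ValueError("n_years must be >= 5")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_years, n_series)),
        index=pd.RangeIndex(1, n_years + 1, name="year"),
        columns=[f"z{i+1}" for i in range(n_series)],
    )


def make_refcon_truth(
    config: GeneratorConfig,
    truth: GroundTruth,
    grace: int = 5,
    kind: RefConKind = RefConKind.refcon_chl,
) -> tuple[RefConWindow, pd.Series]:
    """Reference window and expected year labels implied by the shift.

    Pre-shift years form the reference window and are expected
    in-control; post-shift years beyond a ``grace``-year detection delay
    are expected out-of-control; in-between years carry no expectation
    and are omitted from the labels.  Without a shift the whole series is
    the window.
    """
    years = list(config.years)
    if truth.shift_year is None:
        window = RefConWindow(config.dataset, kind, years[0], years[-1])
        labels = pd.Series("in_control", index=pd.Index(years, name="year"))
        return window, labels
    window = RefConWindow(config.dataset, kind, years[0], truth.shift_year - 1)
    expect: dict[int, str] = {}
    for y in years:
        if y < truth.shift_year:
            expect[y] = "in_control"
        elif y >= truth.shift_year + grace:
            expect[y] = "out_of_control"
    labels = pd.Series(expect, name="expected")
    labels.index.name = "year"
    return window, labels
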
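"""Synthetic state geography and administrative health records.

Generates a municipality registry (health regions nested in four
macroregions, one seat municipality per region) plus four record tables
with the statistical structure the downstream analysis assumes:

* hospitalizations (SIH-SUS-like): one row per admission with residence
  municipality, occurrence municipality, year, age in days;
* live births (SINASC-like): birth weight, gestational age, 5-minute
  Apgar, maternal age;
* infant deaths (SIM-like): age at death in days;
* NICU bed counts (CNES-like): beds per municipality-year, types I-III
  pooled.

The defaults emulate a state of 22 health regions / ~400 municipalities
observed 2008-2019, with admissions concentrated at region seats under a
gravity (distance-decay) destination choice, a ~1% out-of-state share
among displaced admissions, and a neonatal mortality rate declining
across biennia.  All randomness flows from ``SynthParams.seed`` through
named ``numpy`` generators, so identical parameters reproduce identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from neonet.errors import DataValidationError, ParameterError
from neonet.geo import pairwise_distance_matrix

#: Reserved sentinel for occurrence municipalities outside the state.
#: Never present in the registry.
OUT_OF_STATE = 999999

#: Health-region -> macroregion membership for the default 22-region state.
MACROREGIONS_22: dict[str, tuple[int, ...]] = {
    "leste": (1, 2, 3, 4, 5, 6, 21),
    "oeste": (7, 8, 9, 10, 20),
    "noroeste": (11, 12, 13, 14, 15),
    "norte": (16, 17, 18, 19, 22),
}

MACROREGION_NAMES = ("leste", "oeste", "noroeste", "norte")

REGISTRY_COLUMNS = ["code", "name", "region_id", "macroregion",
                    "seat_lat", "seat_lon", "is_region_seat"]
HOSP_COLUMNS = ["residence_code", "occurrence_code", "year", "age_days"]
BIRTH_COLUMNS = ["residence_code", "year", "birth_weight_g",
                 "gestational_age_weeks", "apgar5", "maternal_age_years"]
DEATH_COLUMNS = ["residence_code", "year", "age_at_death_days"]
BED_COLUMNS = ["municipality_code", "year", "nicu_beds"]


def _default_prevalences() -> dict[str, float]:
    # Marginal prevalences among live births: very low birth weight
    # (<1,500 g), gestational age < 28 weeks, 5-minute Apgar <= 7, and
    # maternal age >= 35 years.
    return {
        "low_birth_weight": 0.012,
        "ga_lt28": 0.0045,
        "apgar5_le7": 0.021,
        "maternal_35plus": 0.12,
    }


@dataclass
class SynthParams:
    """Parameters of the synthetic-state generator.

    Probabilities are in [0, 1]; rates are per the unit stated.  The
    defaults describe the study conditions the analysis is designed for:
    a 22-region state with ~400 municipalities, 2008-2019, ~38% of
    neonatal admissions displaced outside the residence municipality,
    ~1% of displaced admissions out of state, and a neonatal death rate
    starting at 8.98/1,000 live births and declining by 0.31 per biennium.
    """

    n_regions: int = 22
    munis_per_region: int = 18
    year_start: int = 2008
    year_end: int = 2019
    admissions_per_muni_year: float = 30.0
    admissions_growth_per_year: float = 0.05
    displacement_prob: float = 0.38
    seat_attraction: float = 150.0
    distance_decay: float = 3.0
    out_of_state_prob: float = 0.01
    neonatal_age_share: float = 0.80
    births_per_muni_year: float = 375.0
    indicator_prevalences: Mapping[str, float] = field(default_factory=_default_prevalences)
    neonatal_death_rate: float = 8.98
    neonatal_death_rate_change: float = -0.31
    postneonatal_death_rate: float = 2.5
    nicu_bed_base: float = 30.0
    nicu_bed_growth: float = 1.0
    nonseat_bed_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ParameterError("n_regions must be >= 1")
        if self.munis_per_region < 1:
            raise ParameterError("munis_per_region must be >= 1")
        if self.year_end < self.year_start:
            raise ParameterError("year_end must be >= year_start")
        if self.admissions_growth_per_year <= -1.0:
            raise ParameterError("admissions_growth_per_year must be > -1")
        for name in ("displacement_prob", "out_of_state_prob",
                     "neonatal_age_share", "nonseat_bed_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name, v in dict(self.indicator_prevalences).items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"prevalence {name!r} must be in [0, 1], got {v}")
        for name in ("admissions_per_muni_year", "births_per_muni_year",
                     "neonatal_death_rate", "postneonatal_death_rate",
                     "nicu_bed_base", "nicu_bed_growth", "seat_attraction"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def with_(self, **kwargs) -> "SynthParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _rng(params: SynthParams, stream: int) -> np.random.Generator:
    # Independent, reproducible stream per table.
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def _macroregion_map(n_regions: int) -> dict[int, str]:
    if n_regions == 22:
        return {r: m for m, regions in MACROREGIONS_22.items() for r in regions}
    # Generic fallback: contiguous blocks of regions, up to 4 macroregions.
    n_macro = min(4, n_regions)
    per = int(np.ceil(n_regions / n_macro))
    return {r: MACROREGION_NAMES[min((r - 1) // per, n_macro - 1)]
            for r in range(1, n_regions + 1)}


# Bounding box of the synthetic state (degrees); a Parana-sized rectangle.
_LON_MIN, _LON_MAX = -54.6, -48.0
_LAT_MIN, _LAT_MAX = -26.7, -22.5

# Macroregion block layout on a 2x2 grid: (col, row) with row 0 = south.
_MACRO_BLOCKS = {"oeste": (0, 0), "leste": (1, 0), "noroeste": (0, 1), "norte": (1, 1)}


def generate_registry(params: SynthParams) -> pd.DataFrame:
    """Lay out the synthetic municipality registry.

    Regions are rectangular patches tiled inside four macroregion blocks;
    each region's seat sits at the centre of its patch and the remaining
    municipalities on a jittered sub-lattice around it.  Codes are unique
    6-digit integers; exactly one seat per region.
    """
    rng = _rng(params, 1)
    macro_of = _macroregion_map(params.n_regions)
    regions_by_macro: dict[str, list[int]] = {}
    for r in range(1, params.n_regions + 1):
        regions_by_macro.setdefault(macro_of[r], []).append(r)

    block_w = (_LON_MAX - _LON_MIN) / 2.0
    block_h = (_LAT_MAX - _LAT_MIN) / 2.0

    rows = []
    code = 410000
    for macro, regions in regions_by_macro.items():
        bc, br = _MACRO_BLOCKS[macro]
        x0 = _LON_MIN + bc * block_w
        y0 = _LAT_MIN + br * block_h
        k = len(regions)
        ncol = int(np.ceil(np.sqrt(k)))
        nrow = int(np.ceil(k / ncol))
        pw, ph = block_w / ncol, block_h / nrow
        for idx, region in enumerate(regions):
            px = x0 + (idx % ncol) * pw
            py = y0 + (idx // ncol) * ph
            cx, cy = px + pw / 2.0, py + ph / 2.0
            m = params.munis_per_region
            # Non-seat municipalities on a jittered grid inside the patch.
            g = int(np.ceil(np.sqrt(m)))
            xs = px + (np.arange(m) % g + 0.5) / g * pw
            ys = py + (np.arange(m) // g + 0.5) / g * ph
            xs = xs + rng.uniform(-0.2, 0.2, m) * pw / g
            ys = ys + rng.uniform(-0.2, 0.2, m) * ph / g
            # The municipality nearest the patch centre becomes the seat
            # and is snapped onto it.
            seat_idx = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
            xs[seat_idx], ys[seat_idx] = cx, cy
            for i in range(m):
                code += 1
                is_seat = i == seat_idx
                name = (f"Sede R{region:02d}" if is_seat
                        else f"Municipio R{region:02d}-{i + 1:02d}")
                rows.append((code, name, region, macro,
                             float(ys[i]), float(xs[i]), is_seat))

    registry = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    registry = registry.sort_values("code", ignore_index=True)
    assert registry["code"].is_unique
    assert registry.groupby("region_id")["is_region_seat"].sum().eq(1).all()
    return registry


def _check_registry(registry: pd.DataFrame) -> None:
    if registry is None or len(registry) == 0:
        raise DataValidationError("registry is empty")


def _sample_ages(rng: np.random.Generator, n: int, neonatal_share: float) -> np.ndarray:
    """Admission ages in days: mass on 0-27 with early-day skew, tail to 1 y."""
    neonatal = rng.random(n) < neonatal_share
    ages = np.empty(n, dtype=np.int64)
    # Within the neonatal window, admissions cluster in the first days of
    # life; exponentially decaying weights over days 0..27.
    days = np.arange(28)
    w = np.exp(-days / 8.0)
    ages[neonatal] = rng.choice(days, size=int(neonatal.sum()), p=w / w.sum())
    ages[~neonatal] = rng.integers(28, 365, size=int((~neonatal).sum()))
    return ages


def generate_hospitalizations(registry: pd.DataFrame,
                              params: SynthParams) -> pd.DataFrame:
    """Draw one row per admission with a gravity destination choice.

    With probability ``displacement_prob`` an admission occurs outside the
    residence municipality; displaced admissions go out of state with
    probability ``out_of_state_prob``, otherwise to an in-state destination
    drawn with weight ``seat_attraction**is_seat * distance**-distance_decay``.
    """
    _check_registry(registry)
    rng = _rng(params, 2)
    codes = registry["code"].to_numpy()
    is_seat = registry["is_region_seat"].to_numpy(dtype=bool)
    n_muni = len(codes)
    years = np.array(params.years)

    # Admission counts per municipality-year; demand grows over the period.
    mean = (params.admissions_per_muni_year
            * (1.0 + params.admissions_growth_per_year) ** (years - params.year_start))
    counts = rng.poisson(np.broadcast_to(mean, (n_muni, len(years))))
    residence = np.repeat(np.repeat(codes, len(years)), counts.ravel())
    year = np.repeat(np.tile(years, n_muni), counts.ravel())
    n = residence.size

    ages = _sample_ages(rng, n, params.neonatal_age_share)

    occurrence = residence.copy()
    displaced = rng.random(n) < params.displacement_prob
    oos = displaced & (rng.random(n) < params.out_of_state_prob)
    occurrence[oos] = OUT_OF_STATE
    instate = displaced & ~oos

    if n_muni > 1 and instate.any():
        dist = pairwise_distance_matrix(registry["seat_lat"].to_numpy(),
                                        registry["seat_lon"].to_numpy())
        attract = np.where(is_seat, params.seat_attraction, 1.0)
        idx_of = {c: i for i, c in enumerate(codes)}
        dest = np.empty(int(instate.sum()), dtype=np.int64)
        res_instate = residence[instate]
        order = np.argsort(res_instate, kind="stable")
        sorted_res = res_instate[order]
        starts = np.searchsorted(sorted_res, codes, side="left")
        ends = np.searchsorted(sorted_res, codes, side="right")
        for i in range(n_muni):
            m = ends[i] - starts[i]
            if m == 0:
                continue
            with np.errstate(divide="ignore"):
                w = attract * dist[i] ** (-params.distance_decay)
            w[i] = 0.0
            w = np.where(np.isfinite(w), w, 0.0)
            p = w / w.sum()
            dest[order[starts[i]:ends[i]]] = rng.choice(codes, size=m, p=p)
        occurrence[instate] = dest
    elif instate.any():
        # Single-municipality registry: nowhere in-state to go.
        occurrence[instate] = residence[instate]

    return pd.DataFrame({
        "residence_code": residence,
        "occurrence_code": occurrence,
        "year": year,
        "age_days": ages,
    })


def generate_vital_records(registry: pd.DataFrame,
                           params: SynthParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Live-birth and infant-death tables with configurable prevalences.

    Births carry birth weight, gestational age, 5-minute Apgar and maternal
    age whose marginal prevalences (very low weight, GA < 28 w, Apgar <= 7,
    age >= 35 y) match ``indicator_prevalences``.  Neonatal deaths (age at
    death 0-27 d) occur at ``neonatal_death_rate`` per 1,000 live births in
    the first biennium, shifted by ``neonatal_death_rate_change`` per
    subsequent biennium; a post-neonatal tail exercises the age filter.
    """
    _check_registry(registry)
    rng = _rng(params, 3)
    prev = {**_default_prevalences(), **dict(params.indicator_prevalences)}
    codes = registry["code"].to_numpy()
    years = np.array(params.years)

    counts = rng.poisson(params.births_per_muni_year, size=(len(codes), len(years)))
    residence = np.repeat(np.repeat(codes, len(years)), counts.ravel())
    year = np.repeat(np.tile(years, len(codes)), counts.ravel())
    n = residence.size

    low = rng.random(n) < prev["low_birth_weight"]
    weight = np.where(low,
                      rng.uniform(500, 1500, n),
                      np.clip(rng.normal(3200, 450, n), 1500, 5500)).round().astype(int)
    ga_low = rng.random(n) < prev["ga_lt28"]
    ga = np.where(ga_low,
                  rng.integers(22, 28, n),
                  np.clip(rng.normal(39, 1.8, n).round(), 28, 43)).astype(int)
    apgar_low = rng.random(n) < prev["apgar5_le7"]
    apgar = np.where(apgar_low, rng.integers(0, 8, n), rng.integers(8, 11, n)).astype(int)
    m35 = rng.random(n) < prev["maternal_35plus"]
    mage = np.where(m35, rng.integers(35, 46, n), rng.integers(15, 35, n)).astype(int)

    births = pd.DataFrame({
        "residence_code": residence,
        "year": year,
        "birth_weight_g": weight,
        "gestational_age_weeks": ga,
        "apgar5": apgar,
        "maternal_age_years": mage,
    })

    # Deaths per municipality-year, thinned from the realized birth counts.
    biennium_idx = (years - params.year_start) // 2  # 0-based
    neo_rate = np.maximum(
        params.neonatal_death_rate + params.neonatal_death_rate_change * biennium_idx,
        0.0)
    neo_counts = rng.poisson(counts * neo_rate[None, :] / 1000.0)
    post_counts = rng.poisson(counts * params.postneonatal_death_rate / 1000.0)

    res_neo = np.repeat(np.repeat(codes, len(years)), neo_counts.ravel())
    yr_neo = np.repeat(np.tile(years, len(codes)), neo_counts.ravel())
    age_neo = np.minimum(rng.geometric(0.25, res_neo.size) - 1, 27)
    res_post = np.repeat(np.repeat(codes, len(years)), post_counts.ravel())
    yr_post = np.repeat(np.tile(years, len(codes)), post_counts.ravel())
    age_post = rng.integers(28, 365, res_post.size)

    deaths = pd.DataFrame({
        "residence_code": np.concatenate([res_neo, res_post]),
        "year": np.concatenate([yr_neo, yr_post]),
        "age_at_death_days": np.concatenate([age_neo, age_post]),
    })
    return births, deaths


def generate_bed_counts(registry: pd.DataFrame, params: SynthParams) -> pd.DataFrame:
    """NICU bed stock per municipality-year, concentrated at region seats.

    Seats hold ``Poisson(nicu_bed_base + nicu_bed_growth * years_elapsed)``
    beds; non-seat municipalities hold a small count with probability
    ``nonseat_bed_prob`` and zero otherwise.
    """
    _check_registry(registry)
    rng = _rng(params, 4)
    codes = registry["code"].to_numpy()
    is_seat = registry["is_region_seat"].to_numpy(dtype=bool)
    years = np.array(params.years)
    elapsed = years - params.year_start

    mean_seat = params.nicu_bed_base + params.nicu_bed_growth * elapsed
    beds = np.zeros((len(codes), len(years)), dtype=np.int64)
    beds[is_seat] = rng.poisson(np.broadcast_to(mean_seat, (int(is_seat.sum()),
                                                            len(years))))
    nonseat = ~is_seat
    has_beds = rng.random(int(nonseat.sum())) < params.nonseat_bed_prob
    small = rng.poisson(3.0, size=(int(has_beds.sum()), len(years)))
    sub = beds[nonseat]
    sub[has_beds] = small
    beds[nonseat] = sub

    return pd.DataFrame({
        "municipality_code": np.repeat(codes, len(years)),
        "year": np.tile(years, len(codes)),
        "nicu_beds": beds.ravel(),
    })


def generate_dataset(params: SynthParams | None = None) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic study: registry plus all four tables."""
    params = params or SynthParams()
    registry = generate_registry(params)
    births, deaths = generate_vital_records(registry, params)
    return {
        "registry": registry,
        "hospitalizations": generate_hospitalizations(registry, params),
        "births": births,
        "deaths": deaths,
        "beds": generate_bed_counts(registry, params),
    }
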
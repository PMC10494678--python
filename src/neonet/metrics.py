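"""Flow-weighted distance statistics and regional indicators.

For each origin municipality :math:`O_i` the *mean outgoing edge*
:math:`d_i` is the distance to its destinations weighted by admission
frequency,

.. math:: d_i = \\frac{\\sum_k f_k\\, d(O_i, D_k)}{\\sum_k f_k},

and for each health region *j* the regional displacement distance
:math:`m_j` is the outflow-weighted mean of the :math:`d_i` over the
region's :math:`n_j` origin municipalities,

.. math:: m_j = \\frac{\\sum_i F_i\\, d_i}{\\sum_i F_i},
          \\qquad F_i = \\sum_k f_k .

The composition is algebraically identical to the single-pass
flow-weighted mean of seat-to-seat distances over all of the region's
displaced records, which the test suite uses as the module's oracle.

The module also computes, per health region x biennium: the share of
neonatal admissions displaced outside the residence municipality, the
share of displaced admissions remaining within the residence health
region, NICU beds per 1,000 live births, maternal / newborn indicators,
the neonatal mortality rate (TMN, deaths at 0-27 days per 1,000 live
births), and percent variation between two biennia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neonet.displacement import (NEONATAL_MAX_AGE_DAYS, biennium_labels,
                                 normalize_codes)
from neonet.errors import DataValidationError
from neonet.geo import great_circle_km
from neonet.synth import OUT_OF_STATE

SUMMARY_COLUMNS = [
    "region_id", "biennium_label", "m_j", "n_j", "total_outflow",
    "pct_displaced", "pct_same_region", "nicu_beds_per_1000",
    "pct_low_weight", "pct_ga_lt28", "pct_apgar5_le7", "pct_maternal_35plus",
    "tmn",
]


def percent_variation(a, b):
    """Percent variation ``100 * (B - A) / A`` between two periods.

    A zero baseline leaves the variation undefined and is reported as
    missing (NaN).  Accepts scalars or arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vp = np.where(a == 0.0, np.nan, 100.0 * (b - a) / a)
    if np.ndim(vp) == 0:
        return float(vp)
    return vp


@dataclass(frozen=True)
class OriginSummary:
    """Outflow and flow-weighted mean distance of one origin municipality."""

    origin_code: int
    biennium_label: str
    total_outflow: int  # F_i
    mean_edge_km: float  # d_i


def _od_with_distances(od: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Attach origin/destination region ids and seat-to-seat distances."""
    geo = registry[["code", "region_id", "seat_lat", "seat_lon"]]
    missing = set(od["origin_code"]).union(od["destination_code"]) - set(geo["code"])
    if missing:
        raise DataValidationError(
            f"OD endpoints absent from registry: {sorted(missing)[:5]}")
    out = (od.merge(geo.add_prefix("o_"), left_on="origin_code", right_on="o_code")
             .merge(geo.add_prefix("d_"), left_on="destination_code", right_on="d_code"))
    out["distance_km"] = great_circle_km(out["o_seat_lat"], out["o_seat_lon"],
                                         out["d_seat_lat"], out["d_seat_lon"])
    return out


def origin_mean_edge(pairs: pd.DataFrame, registry: pd.DataFrame) -> OriginSummary:
    """Compute F_i and d_i for the OD pairs of a single origin and biennium."""
    if len(pairs) == 0:
        raise DataValidationError("origin_mean_edge requires at least one OD pair")
    if pairs["origin_code"].nunique() != 1 or pairs["biennium_label"].nunique() != 1:
        raise DataValidationError("pairs must belong to one origin and one biennium")
    d = _od_with_distances(pairs, registry)
    flow = d["flow"].to_numpy(dtype=float)
    dist = d["distance_km"].to_numpy()
    total = flow.sum()
    return OriginSummary(
        origin_code=int(pairs["origin_code"].iloc[0]),
        biennium_label=str(pairs["biennium_label"].iloc[0]),
        total_outflow=int(total),
        mean_edge_km=float((flow * dist).sum() / total),
    )


def origin_summaries(od: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """All-origin version of :func:`origin_mean_edge` (one row per
    origin x biennium, columns origin_code, biennium_label, region_id,
    total_outflow, mean_edge_km)."""
    d = _od_with_distances(od, registry)
    d["wdist"] = d["flow"] * d["distance_km"]
    g = (d.groupby(["origin_code", "biennium_label", "o_region_id"], as_index=False)
           .agg(total_outflow=("flow", "sum"), wdist=("wdist", "sum")))
    g["mean_edge_km"] = g["wdist"] / g["total_outflow"]
    return (g.rename(columns={"o_region_id": "region_id"})
             .drop(columns="wdist")
             [["origin_code", "biennium_label", "region_id",
               "total_outflow", "mean_edge_km"]])


def region_weighted_distance(summaries: pd.DataFrame) -> float:
    """m_j: outflow-weighted mean of d_i over one region-biennium's origins.

    ``summaries`` must carry ``total_outflow`` (F_i) and ``mean_edge_km``
    (d_i); an empty input (region with no displaced flow) is undefined and
    returns NaN.
    """
    if len(summaries) == 0:
        return float("nan")
    f = summaries["total_outflow"].to_numpy(dtype=float)
    d = summaries["mean_edge_km"].to_numpy(dtype=float)
    return float((f * d).sum() / f.sum())


def _with_region(df: pd.DataFrame, registry: pd.DataFrame,
                 code_col: str) -> pd.DataFrame:
    region = registry.set_index("code")["region_id"]
    out = df.copy()
    out["region_id"] = pd.Series(normalize_codes(df[code_col]),
                                 index=df.index).map(region)
    if out["region_id"].isna().any():
        bad = sorted(df.loc[out["region_id"].isna(), code_col].unique())[:5]
        raise DataValidationError(f"codes absent from registry: {bad}")
    return out


def pct_displaced_table(neonatal_records: pd.DataFrame,
                        registry: pd.DataFrame) -> pd.DataFrame:
    """Share (%) of in-state neonatal admissions of each region's residents
    occurring outside the residence municipality, per region x biennium."""
    rec = neonatal_records.copy()
    rec["occurrence_code"] = normalize_codes(rec["occurrence_code"])
    rec["residence_code"] = normalize_codes(rec["residence_code"])
    rec = rec[rec["occurrence_code"] != OUT_OF_STATE]
    rec = _with_region(rec, registry, "residence_code")
    rec["biennium_label"] = biennium_labels(rec["year"]).to_numpy()
    rec["displaced"] = rec["occurrence_code"] != rec["residence_code"]
    g = (rec.groupby(["region_id", "biennium_label"], as_index=False)
            .agg(n=("displaced", "size"), displaced=("displaced", "sum")))
    g["pct_displaced"] = 100.0 * g["displaced"] / g["n"]
    return g[["region_id", "biennium_label", "pct_displaced"]]


def pct_same_region_table(od: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Share (%) of displaced admissions whose destination lies in the same
    health region as the origin, per origin region x biennium.

    The denominator is displaced admissions only (total displaced outflow
    of the region's origins), not all admissions.
    """
    d = _od_with_distances(od, registry)
    d["same"] = (d["o_region_id"] == d["d_region_id"]).astype(float) * d["flow"]
    g = (d.groupby(["o_region_id", "biennium_label"], as_index=False)
           .agg(flow=("flow", "sum"), same=("same", "sum")))
    g["pct_same_region"] = 100.0 * g["same"] / g["flow"]
    return (g.rename(columns={"o_region_id": "region_id"})
             [["region_id", "biennium_label", "pct_same_region"]])


def compute_indicators(births: pd.DataFrame, deaths: pd.DataFrame,
                       beds: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Maternal/newborn indicators per region x biennium.

    Proportions are 100 x qualifying births / total births; TMN is neonatal
    deaths (age <= 27 d) per 1,000 live births; NICU beds per 1,000 live
    births use the bed stock averaged over the biennium's two year-end
    counts.  Cells with zero births are missing.
    """
    b = _with_region(births, registry, "residence_code")
    b["biennium_label"] = biennium_labels(b["year"]).to_numpy()

    bed = _with_region(beds, registry, "municipality_code")
    bed["biennium_label"] = biennium_labels(bed["year"]).to_numpy()

    # Full region x biennium grid, so zero-birth cells appear as missing
    # rows rather than silently vanishing.
    labels = sorted(set(b["biennium_label"]).union(bed["biennium_label"]))
    grid = pd.MultiIndex.from_product(
        [sorted(registry["region_id"].unique()), labels],
        names=["region_id", "biennium_label"])

    g = (b.groupby(["region_id", "biennium_label"]).agg(
            births=("year", "size"),
            low=("birth_weight_g", lambda s: (s < 1500).sum()),
            ga=("gestational_age_weeks", lambda s: (s < 28).sum()),
            apgar=("apgar5", lambda s: (s <= 7).sum()),
            m35=("maternal_age_years", lambda s: (s >= 35).sum()))
         .reindex(grid, fill_value=0))

    d = _with_region(deaths, registry, "residence_code")
    d = d[d["age_at_death_days"] <= NEONATAL_MAX_AGE_DAYS]
    d["biennium_label"] = biennium_labels(d["year"]).to_numpy()
    g["neo_deaths"] = (d.groupby(["region_id", "biennium_label"]).size()
                        .reindex(g.index, fill_value=0))

    # Region-level stock per year, then mean of the biennium's two years.
    yearly = (bed.groupby(["region_id", "biennium_label", "year"])["nicu_beds"]
                 .sum().groupby(["region_id", "biennium_label"]).mean())
    g["beds"] = yearly.reindex(g.index)

    g = g.reset_index()
    births_n = np.where(g["births"] > 0, g["births"].astype(float), np.nan)
    g["pct_low_weight"] = 100.0 * g["low"] / births_n
    g["pct_ga_lt28"] = 100.0 * g["ga"] / births_n
    g["pct_apgar5_le7"] = 100.0 * g["apgar"] / births_n
    g["pct_maternal_35plus"] = 100.0 * g["m35"] / births_n
    g["tmn"] = 1000.0 * g["neo_deaths"] / births_n
    g["nicu_beds_per_1000"] = 1000.0 * g["beds"] / births_n
    return g[["region_id", "biennium_label", "nicu_beds_per_1000",
              "pct_low_weight", "pct_ga_lt28", "pct_apgar5_le7",
              "pct_maternal_35plus", "tmn"]]


def summarize_regions(neonatal_records: pd.DataFrame, od: pd.DataFrame,
                      births: pd.DataFrame, deaths: pd.DataFrame,
                      beds: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """The region x biennium summary table feeding Tables 2-4 analogues.

    One row per health region x biennium with the flow-weighted distance
    m_j, origin count n_j, displacement shares, service-supply and
    maternal/newborn indicators, and TMN.  Region-biennium cells with no
    displaced flow carry missing distance metrics, never zero.
    """
    summ = origin_summaries(od, registry)
    summ["wd"] = summ["total_outflow"] * summ["mean_edge_km"]
    dist = (summ.groupby(["region_id", "biennium_label"], as_index=False)
                .agg(n_j=("origin_code", "nunique"),
                     total_outflow=("total_outflow", "sum"),
                     wd=("wd", "sum")))
    dist["m_j"] = dist["wd"] / dist["total_outflow"]
    dist = dist.drop(columns="wd")

    base = compute_indicators(births, deaths, beds, registry)
    out = (base.merge(dist, on=["region_id", "biennium_label"], how="left")
               .merge(pct_displaced_table(neonatal_records, registry),
                      on=["region_id", "biennium_label"], how="left")
               .merge(pct_same_region_table(od, registry),
                      on=["region_id", "biennium_label"], how="left"))
    return (out[SUMMARY_COLUMNS]
            .sort_values(["region_id", "biennium_label"], ignore_index=True))


def variation_table(summary: pd.DataFrame, biennium_a: str, biennium_b: str,
                    columns: tuple[str, ...] = ("m_j", "pct_displaced",
                                                "pct_same_region")) -> pd.DataFrame:
    """Percent variation of summary columns between two biennia, per region."""
    a = summary[summary["biennium_label"] == biennium_a].set_index("region_id")
    b = summary[summary["biennium_label"] == biennium_b].set_index("region_id")
    out = pd.DataFrame(index=a.index.union(b.index))
    for col in columns:
        out[f"{col}_a"] = a[col]
        out[f"{col}_b"] = b[col]
        out[f"{col}_vp"] = percent_variation(out[f"{col}_a"].to_numpy(),
                                             out[f"{col}_b"].to_numpy())
    return out.reset_index().rename(columns={"index": "region_id"})
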
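"""Flow-weighted distances, regional indicators, percent variation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neonet as nn
from neonet.errors import DataValidationError
from neonet.geo import EARTH_RADIUS_KM
from neonet.metrics import (compute_indicators, origin_summaries,
                            pct_displaced_table, pct_same_region_table,
                            variation_table)

KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def meridian_registry(km_offsets, region_ids=None, seats=None):
    """Municipalities along one meridian so seat-to-seat distances are exact."""
    n = len(km_offsets)
    region_ids = region_ids or [1] * n
    seats = seats or [i == 0 for i in range(n)]
    return pd.DataFrame({
        "code": [410001 + i for i in range(n)],
        "name": [f"M{i}" for i in range(n)],
        "region_id": region_ids,
        "macroregion": ["leste"] * n,
        "seat_lat": [km / KM_PER_DEG for km in km_offsets],
        "seat_lon": [0.0] * n,
        "is_region_seat": seats,
    })


def od(rows):
    return pd.DataFrame(rows, columns=["origin_code", "destination_code",
                                       "biennium_label", "flow"])


class TestPercentVariation:
    @pytest.mark.parametrize("a,b,expected", [
        (123.18, 59.86, -51.40),   # regional distance drop
        (13, 273, 2000.00),        # inflow jump
        (380, 2571, 576.58),
        (2740, 2255, -17.70),
        (7, 4, -42.86),
        (4, 49, 1125.00),
        (40, 612, 1430.00),
        (18.93, 86.85, 358.80),
    ])
    def test_printed_two_decimal_examples(self, a, b, expected):
        assert nn.percent_variation(a, b) == pytest.approx(expected, abs=0.01)

    def test_no_change_is_zero(self):
        assert nn.percent_variation(3.7, 3.7) == 0.0

    def test_zero_baseline_is_missing(self):
        assert np.isnan(nn.percent_variation(0.0, 5.0))

    @given(a=st.floats(0.01, 1e6), b=st.floats(0, 1e6))
    def test_sign_matches_direction_of_change(self, a, b):
        vp = nn.percent_variation(a, b)
        assert np.sign(vp) == np.sign(b - a)

    def test_vectorized(self):
        np.testing.assert_allclose(nn.percent_variation([10, 0], [15, 3]),
                                   [50.0, np.nan])


class TestOriginMeanEdge:
    def test_single_destination_any_flow(self):
        reg = meridian_registry([0.0, 42.0])
        for flow in (1, 7):
            s = nn.origin_mean_edge(od([(410001, 410002, "2008-2009", flow)]), reg)
            assert s.mean_edge_km == pytest.approx(42.0, abs=1e-9)
            assert s.total_outflow == flow

    def test_weighted_mean_of_two_destinations(self):
        # flows (1,3) at 10 and 20 km -> (1*10+3*20)/4 = 17.5
        reg = meridian_registry([0.0, 10.0, 20.0])
        s = nn.origin_mean_edge(od([(410001, 410002, "2008-2009", 1),
                                    (410001, 410003, "2008-2009", 3)]), reg)
        assert s.mean_edge_km == pytest.approx(17.5, abs=1e-9)
        assert s.total_outflow == 4

    def test_empty_and_mixed_inputs_rejected(self):
        reg = meridian_registry([0.0, 10.0])
        with pytest.raises(DataValidationError):
            nn.origin_mean_edge(od([]), reg)
        with pytest.raises(DataValidationError):
            nn.origin_mean_edge(od([(410001, 410002, "2008-2009", 1),
                                    (410002, 410001, "2008-2009", 1)]), reg)

    def test_matches_record_level_expansion_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_dest = rng.integers(1, 9)
            offsets = [0.0, *rng.uniform(5, 300, n_dest)]
            reg = meridian_registry(offsets)
            flows = rng.integers(1, 20, n_dest)
            pairs = od([(410001, 410002 + i, "2010-2011", int(f))
                        for i, f in enumerate(flows)])
            s = nn.origin_mean_edge(pairs, reg)
            # brute force: expand each pair to unit records, plain mean
            unit = np.repeat(np.array(offsets[1:]), flows)
            assert s.mean_edge_km == pytest.approx(unit.mean(), rel=1e-9)
            assert min(offsets[1:]) - 1e-9 <= s.mean_edge_km <= max(offsets[1:]) + 1e-9


class TestRegionWeightedDistance:
    def test_single_origin_passes_through(self):
        s = pd.DataFrame({"total_outflow": [5], "mean_edge_km": [33.3]})
        assert nn.region_weighted_distance(s) == pytest.approx(33.3)

    def test_equal_weights_are_plain_mean(self):
        s = pd.DataFrame({"total_outflow": [2, 2], "mean_edge_km": [10.0, 30.0]})
        assert nn.region_weighted_distance(s) == pytest.approx(20.0)

    def test_zero_flow_region_is_missing(self):
        assert np.isnan(nn.region_weighted_distance(
            pd.DataFrame({"total_outflow": [], "mean_edge_km": []})))

    def test_two_level_equals_single_pass_record_mean(self, small_data,
                                                      small_registry):
        # The module's main oracle: Eq-composition == flow-weighted mean of
        # seat-to-seat distances over all the region's displaced records.
        neo = nn.filter_neonatal(small_data["hospitalizations"])
        displaced, _, _, _ = nn.partition_displaced(neo, small_registry)
        odt = nn.aggregate_od(displaced)
        summ = origin_summaries(odt, small_registry)
        geo = small_registry.set_index("code")
        for (region, bl), grp in summ.groupby(["region_id", "biennium_label"]):
            m_j = nn.region_weighted_distance(grp)
            sub = odt[(odt["biennium_label"] == bl)
                      & (odt["origin_code"].map(geo["region_id"]) == region)]
            d = nn.great_circle_km(
                sub["origin_code"].map(geo["seat_lat"]).to_numpy(),
                sub["origin_code"].map(geo["seat_lon"]).to_numpy(),
                sub["destination_code"].map(geo["seat_lat"]).to_numpy(),
                sub["destination_code"].map(geo["seat_lon"]).to_numpy())
            oracle = np.average(d, weights=sub["flow"])
            assert m_j == pytest.approx(oracle, rel=1e-9)

    def test_scale_equivariance_in_flows(self, small_data, small_registry):
        neo = nn.filter_neonatal(small_data["hospitalizations"])
        displaced, _, _, _ = nn.partition_displaced(neo, small_registry)
        odt = nn.aggregate_od(displaced)
        scaled = odt.assign(flow=odt["flow"] * 7)
        a = origin_summaries(odt, small_registry)
        b = origin_summaries(scaled, small_registry)
        np.testing.assert_allclose(a["mean_edge_km"], b["mean_edge_km"])
        pa = pct_same_region_table(odt, small_registry)
        pb = pct_same_region_table(scaled, small_registry)
        np.testing.assert_allclose(pa["pct_same_region"], pb["pct_same_region"])


class TestShares:
    def test_all_or_none_displaced(self):
        reg = meridian_registry([0.0, 10.0], region_ids=[1, 1],
                                seats=[True, False])
        rec = pd.DataFrame({"residence_code": [410001] * 4,
                            "occurrence_code": [410002] * 4,
                            "year": [2008] * 4, "age_days": [0] * 4})
        t = pct_displaced_table(rec, reg)
        assert t["pct_displaced"].iloc[0] == 100.0
        rec["occurrence_code"] = 410001
        t = pct_displaced_table(rec, reg)
        assert t["pct_displaced"].iloc[0] == 0.0

    def test_same_region_share_extremes(self):
        reg = meridian_registry([0.0, 10.0, 20.0], region_ids=[1, 1, 2],
                                seats=[True, False, True])
        inside = od([(410001, 410002, "2008-2009", 5)])
        outside = od([(410001, 410003, "2008-2009", 5)])
        assert pct_same_region_table(inside, reg)["pct_same_region"].iloc[0] == 100.0
        assert pct_same_region_table(outside, reg)["pct_same_region"].iloc[0] == 0.0

    def test_shares_match_brute_force_recount(self, small_data, small_registry):
        neo = nn.filter_neonatal(small_data["hospitalizations"])
        displaced, same, _, _ = nn.partition_displaced(neo, small_registry)
        odt = nn.aggregate_od(displaced)
        region_of = small_registry.set_index("code")["region_id"]
        t = pct_displaced_table(neo, small_registry).set_index(
            ["region_id", "biennium_label"])
        # brute force one cell
        region, bl = t.index[0]
        instate = neo[neo["occurrence_code"] != nn.OUT_OF_STATE]
        mask = ((instate["residence_code"].map(region_of) == region)
                & (instate["year"].map(lambda y: nn.assign_biennium(y).label) == bl))
        sub = instate[mask]
        expected = 100.0 * (sub["occurrence_code"]
                            != sub["residence_code"]).sum() / len(sub)
        assert t.loc[(region, bl), "pct_displaced"] == pytest.approx(expected)

        s = pct_same_region_table(odt, small_registry).set_index(
            ["region_id", "biennium_label"])
        sub = odt[(odt["origin_code"].map(region_of) == region)
                  & (odt["biennium_label"] == bl)]
        expected = 100.0 * sub.loc[sub["destination_code"].map(region_of)
                                   == region, "flow"].sum() / sub["flow"].sum()
        assert s.loc[(region, bl), "pct_same_region"] == pytest.approx(expected)


class TestIndicators:
    def make_births(self, n, code=410001, year=2008):
        return pd.DataFrame({
            "residence_code": [code] * n, "year": [year] * n,
            "birth_weight_g": [3000] * n, "gestational_age_weeks": [39] * n,
            "apgar5": [9] * n, "maternal_age_years": [25] * n,
        })

    def test_one_death_per_thousand_births(self):
        reg = meridian_registry([0.0])
        births = self.make_births(1000)
        deaths = pd.DataFrame({"residence_code": [410001],
                               "year": [2008], "age_at_death_days": [3]})
        beds = pd.DataFrame({"municipality_code": [410001], "year": [2008],
                             "nicu_beds": [0]})
        ind = compute_indicators(births, deaths, beds, reg)
        assert ind["tmn"].iloc[0] == pytest.approx(1.0)
        assert ind["pct_apgar5_le7"].iloc[0] == 0.0

    def test_postneonatal_deaths_not_counted(self):
        reg = meridian_registry([0.0])
        births = self.make_births(1000)
        deaths = pd.DataFrame({"residence_code": [410001, 410001],
                               "year": [2008, 2008],
                               "age_at_death_days": [27, 28]})
        beds = pd.DataFrame({"municipality_code": [410001], "year": [2008],
                             "nicu_beds": [0]})
        ind = compute_indicators(births, deaths, beds, reg)
        assert ind["tmn"].iloc[0] == pytest.approx(1.0)

    def test_beds_averaged_over_biennium_years(self):
        reg = meridian_registry([0.0])
        births = pd.concat([self.make_births(500, year=2008),
                            self.make_births(500, year=2009)],
                           ignore_index=True)
        deaths = pd.DataFrame(columns=["residence_code", "year",
                                       "age_at_death_days"]).astype(int)
        beds = pd.DataFrame({"municipality_code": [410001, 410001],
                             "year": [2008, 2009], "nicu_beds": [10, 20]})
        ind = compute_indicators(births, deaths, beds, reg)
        # mean stock 15 over 1000 births -> 15 per 1,000
        assert ind["nicu_beds_per_1000"].iloc[0] == pytest.approx(15.0)

    def test_zero_birth_cell_is_missing(self):
        reg = meridian_registry([0.0, 10.0], region_ids=[1, 2],
                                seats=[True, True])
        births = self.make_births(100)  # region 1 only
        deaths = pd.DataFrame(columns=["residence_code", "year",
                                       "age_at_death_days"]).astype(int)
        beds = pd.DataFrame({"municipality_code": [410002], "year": [2008],
                             "nicu_beds": [5]})
        ind = compute_indicators(births, deaths, beds, reg).set_index("region_id")
        assert np.isnan(ind.loc[2, "tmn"])
        assert np.isnan(ind.loc[2, "nicu_beds_per_1000"])

    def test_prevalences_recovered_within_3se(self, small_data, small_registry):
        params = nn.SynthParams()
        prev = dict(params.indicator_prevalences)
        births = small_data["births"]
        n = len(births)
        checks = {
            "pct_low_weight": ("low_birth_weight",
                               (births["birth_weight_g"] < 1500)),
            "pct_ga_lt28": ("ga_lt28", (births["gestational_age_weeks"] < 28)),
            "pct_apgar5_le7": ("apgar5_le7", (births["apgar5"] <= 7)),
            "pct_maternal_35plus": ("maternal_35plus",
                                    (births["maternal_age_years"] >= 35)),
        }
        for _, (key, mask) in checks.items():
            p = prev[key]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(mask.mean() - p) < 3 * se


class TestSummaryTable:
    def test_summary_schema_and_bounds(self, small_data, small_registry):
        neo = nn.filter_neonatal(small_data["hospitalizations"])
        displaced, _, _, _ = nn.partition_displaced(neo, small_registry)
        odt = nn.aggregate_od(displaced)
        summ = nn.summarize_regions(neo, odt, small_data["births"],
                                    small_data["deaths"], small_data["beds"],
                                    small_registry)
        n_regions = small_registry["region_id"].nunique()
        assert len(summ) == n_regions * 6
        pct_cols = ["pct_displaced", "pct_same_region", "pct_low_weight",
                    "pct_ga_lt28", "pct_apgar5_le7", "pct_maternal_35plus"]
        for col in pct_cols:
            vals = summ[col].dropna()
            assert vals.between(0, 100).all()
        assert (summ["tmn"].dropna() >= 0).all()
        assert summ["m_j"].notna().all()  # every region has displaced flow here

    def test_variation_table_consistency(self, small_data, small_registry):
        neo = nn.filter_neonatal(small_data["hospitalizations"])
        displaced, _, _, _ = nn.partition_displaced(neo, small_registry)
        odt = nn.aggregate_od(displaced)
        summ = nn.summarize_regions(neo, odt, small_data["births"],
                                    small_data["deaths"], small_data["beds"],
                                    small_registry)
        vt = variation_table(summ, "2008-2009", "2018-2019").set_index("region_id")
        row = summ[(summ["region_id"] == vt.index[0])]
        a = row.loc[row["biennium_label"] == "2008-2009", "m_j"].iloc[0]
        b = row.loc[row["biennium_label"] == "2018-2019", "m_j"].iloc[0]
        assert vt["m_j_vp"].iloc[0] == pytest.approx(nn.percent_variation(a, b))
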
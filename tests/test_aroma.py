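import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peachferm import (
    OdorThresholds,
    VolatileTable,
    band_of,
    cluster_volatile_profiles,
    compute_oav,
    oav_band_agreement,
    quantify_internal_standard,
)


class TestInternalStandard:
    def test_identity_ratio(self):
        np.testing.assert_allclose(quantify_internal_standard([100.0], 100.0, 6000.0), [6000.0])

    def test_study_spike_arithmetic(self):
        # 2 uL of 30 mg/mL into 10 mL -> 6 mg/L = 6000 ug/L
        is_conc = 2e-3 * 30_000 / 10  # mL * ug/mL / mL -> ug/mL... in ug/L:
        assert 2e-3 * 30.0 / 10.0 * 1e6 == pytest.approx(6000.0)
        np.testing.assert_allclose(quantify_internal_standard([50.0], 100.0, 6000.0), [3000.0])

    def test_linearity(self):
        a = quantify_internal_standard([10.0, 20.0], 5.0, 100.0)
        assert a[1] == pytest.approx(2 * a[0])

    def test_nonpositive_is_area_rejected(self):
        with pytest.raises(ValueError):
            quantify_internal_standard([1.0], 0.0, 100.0)


class TestBanding:
    @pytest.mark.parametrize("oav,band", [
        (0.0999999, "<0.1"), (0.1, "0.1-1"), (0.5, "0.1-1"),
        (1.0, "0.1-1"), (1.0000001, ">1"), (14.25, ">1"), (0.0, "<0.1"),
    ])
    def test_boundaries(self, oav, band):
        assert band_of(oav) == band

    def test_undefined_oav_has_no_band(self):
        assert band_of(float("nan")) is None

    @given(st.floats(min_value=0, max_value=100, allow_nan=False),
           st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_band_is_monotone_step(self, a, b):
        lo, hi = sorted((a, b))
        order = {"<0.1": 0, "0.1-1": 1, ">1": 2}
        assert order[band_of(lo)] <= order[band_of(hi)]


def _mini_table():
    conc = pd.DataFrame({"x": [10.0, 40.0], "y": [np.nan, 5.0]}, index=["A", "F"])
    classes = pd.Series({"x": "ester", "y": "alcohol"})
    th = OdorThresholds(pd.DataFrame(
        {"threshold_low": [20.0, np.nan], "threshold_high": [40.0, np.nan]},
        index=["x", "y"]))
    return VolatileTable(conc, classes), th


class TestComputeOav:
    @pytest.mark.parametrize("compound,expected_oav,expected_band", [
        ("Ethyl hexanoate", 71.25 / 5, ">1"),
        ("Hexyl acetate", 60.26 / 670, "<0.1"),
        ("γ-Decalactone", 110.02 / 1.1, ">1"),
        ("Ethyl caprylate", 190.71 / 5, ">1"),
    ])
    def test_final_stage_fixture_values(self, fixture_tables, compound,
                                        expected_oav, expected_band):
        vt, th = fixture_tables
        rec = {r.compound: r for r in compute_oav(vt, th, "F")}[compound]
        assert rec.oav == pytest.approx(expected_oav, rel=1e-9)
        assert rec.band == expected_band

    def test_concentration_equal_threshold_lands_in_middle_band(self):
        v, th = _mini_table()
        v.concentrations.at["F", "x"] = 20.0
        rec = {r.compound: r for r in compute_oav(v, th, "F")}["x"]
        assert rec.oav == pytest.approx(1.0)
        assert rec.band == "0.1-1"

    def test_threshold_policy_switch(self):
        v, th = _mini_table()
        low = {r.compound: r for r in compute_oav(v, th, "F", "low")}["x"]
        high = {r.compound: r for r in compute_oav(v, th, "F", "high")}["x"]
        assert low.oav == pytest.approx(2.0)
        assert high.oav == pytest.approx(1.0)

    def test_missing_threshold_yields_undefined_oav(self):
        v, th = _mini_table()
        rec = {r.compound: r for r in compute_oav(v, th, "F")}["y"]
        assert np.isnan(rec.oav) and rec.band is None

    def test_unknown_stage_rejected(self, fixture_tables):
        vt, th = fixture_tables
        with pytest.raises(ValueError, match="stage"):
            compute_oav(vt, th, "Z")

    def test_scale_equivariance(self, fixture_tables):
        vt, th = fixture_tables
        scaled_v = VolatileTable(vt.concentrations * 7.0, vt.compound_class)
        scaled_th = OdorThresholds(th.table * 7.0)
        a = {r.compound: r.band for r in compute_oav(vt, th, "F")}
        b = {r.compound: r.band for r in compute_oav(scaled_v, scaled_th, "F")}
        assert a == b


class TestBandAgreement:
    def test_ethanol_flagged_as_known_mismatch(self, fixture_tables):
        vt, th = fixture_tables
        rep = oav_band_agreement(vt, th, "F")
        bad = rep[rep["status"] == "mismatch"]
        assert list(bad["compound"]) == ["Ethanol"]
        assert bad.iloc[0]["computed_band"] == "0.1-1"
        assert bad.iloc[0]["printed_band"] == ">1"

    def test_gamma_decalactone_matches(self, fixture_tables):
        vt, th = fixture_tables
        rep = oav_band_agreement(vt, th, "F").set_index("compound")
        assert rep.at["γ-Decalactone", "status"] == "match"

    def test_table_without_printed_bands_reports_not_printed(self):
        v, th = _mini_table()
        rep = oav_band_agreement(v, th, "F")
        assert set(rep["status"]) <= {"not_printed"}


class TestClustering:
    def test_identical_profiles_co_cluster(self):
        conc = pd.DataFrame(
            {"p": [1, 5, 9], "q": [2, 10, 18], "r": [9, 5, 1], "s": [8, 4, 2]},
            index=["A", "B", "C"], dtype=float)
        v = VolatileTable(conc, pd.Series("ester", index=conc.columns))
        cl = cluster_volatile_profiles(v, k=2)
        assert cl["p"] == cl["q"]
        assert cl["r"] == cl["s"]
        assert cl["p"] != cl["r"]

    def test_early_only_aldehydes_co_cluster_on_fixture(self, fixture_tables):
        vt, _ = fixture_tables
        cl = cluster_volatile_profiles(vt, k=2)
        assert cl["Hexanal"] == cl["2-Hexenal"]

    def test_invariant_to_compound_ordering(self, fixture_tables):
        vt, _ = fixture_tables
        shuffled = VolatileTable(vt.concentrations.iloc[:, ::-1], vt.compound_class)
        a = cluster_volatile_profiles(vt, k=2)
        b = cluster_volatile_profiles(shuffled, k=2)
        # same partition (labels may swap)
        pairs_a = {(c1, c2) for c1 in a.index for c2 in a.index if a[c1] == a[c2]}
        pairs_b = {(c1, c2) for c1 in b.index for c2 in b.index if b[c1] == b[c2]}
        assert pairs_a == pairs_b

    def test_bad_k_rejected(self, fixture_tables):
        vt, _ = fixture_tables
        with pytest.raises(ValueError):
            cluster_volatile_profiles(vt, k=1)
        with pytest.raises(ValueError):
            cluster_volatile_profiles(vt, k=54)
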
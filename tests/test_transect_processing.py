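"""Reduction chain: blank, drift, quantification, ratios, summaries, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otolith_origin.errors import ReductionError, SummaryError
from otolith_origin.transect_processing import (
    CHANNELS,
    MACS3_CERTIFIED_UGG,
    MW,
    StandardSeries,
    correct_drift,
    flag_vaterite,
    quantify,
    reduce_transect,
    subtract_blank,
    summarize,
    to_molar_ratio,
)

BLANK0 = {"sr": 0.0, "mg": 0.0, "ca": 0.0}


def _standards_df(factors=(1.0,)):
    """Standard blocks whose sensitivities scale by the given factors."""
    rows = []
    for b, f in enumerate(factors):
        for rep in range(3):
            rows.append(dict(block_index=b, position=float(b), replicate=rep,
                             sr=MACS3_CERTIFIED_UGG["sr"] * f,
                             mg=MACS3_CERTIFIED_UGG["mg"] * f,
                             ca=MACS3_CERTIFIED_UGG["ca"] * f))
    return pd.DataFrame(rows)


def _points(sr=1000.0, mg=500.0, ca=2000.0, n=5):
    d = np.arange(n) * 5.0
    return pd.DataFrame({"distance_um": d, "sr": sr, "mg": mg, "ca": ca})


class TestBlankSubtraction:
    def test_zero_blank_is_identity(self):
        pts = _points()
        out = subtract_blank(pts, BLANK0)
        pd.testing.assert_frame_equal(out, pts)

    def test_subtraction_and_floor(self):
        pts = _points(sr=1000.0, mg=50.0)
        out = subtract_blank(pts, {"sr": 100.0, "mg": 100.0, "ca": 0.0})
        assert (out["sr"] == 900.0).all()
        assert (out["mg"] == 0.0).all()  # floored, not negative

    def test_missing_channel_blank_rejected(self):
        with pytest.raises(ReductionError):
            subtract_blank(_points(), {"sr": 0.0, "mg": 0.0})


class TestDriftCorrection:
    def test_identical_blocks_are_identity(self):
        std = StandardSeries(_standards_df((1.0, 1.0)), BLANK0)
        pts = _points()
        out = correct_drift(pts, std, position=0.5)
        for ch in CHANNELS:
            assert out[ch].to_numpy() == pytest.approx(pts[ch].to_numpy())

    def test_midpoint_interpolates_sensitivity(self):
        std = StandardSeries(_standards_df((1.0, 1.2)), BLANK0)
        out = correct_drift(_points(sr=1100.0), std, position=0.5)
        assert out["sr"].to_numpy() == pytest.approx(1000.0)

    def test_constant_extrapolation_outside_blocks(self):
        std = StandardSeries(_standards_df((1.0, 1.2)), BLANK0)
        out = correct_drift(_points(sr=1200.0), std, position=5.0)
        assert out["sr"].to_numpy() == pytest.approx(1000.0)

    def test_zero_standard_counts_rejected(self):
        df = _standards_df((1.0,))
        df["sr"] = 0.0
        with pytest.raises(ReductionError):
            StandardSeries(df, BLANK0)


class TestQuantification:
    def test_macs3_ratios_recover_certified_scaled_by_assumed_ca(self):
        std = StandardSeries(_standards_df(), BLANK0)
        pts = _points(sr=MACS3_CERTIFIED_UGG["sr"], mg=MACS3_CERTIFIED_UGG["mg"],
                      ca=MACS3_CERTIFIED_UGG["ca"])
        out = quantify(pts, std, ca_internal_pct=38.8)
        expect_sr = MACS3_CERTIFIED_UGG["sr"] / MACS3_CERTIFIED_UGG["ca"] * 388000.0
        assert out["sr_ugg"].to_numpy() == pytest.approx(expect_sr)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_of_ratio_method(self, c):
        std = StandardSeries(_standards_df(), BLANK0)
        pts = _points()
        scaled = pts.copy()
        for ch in CHANNELS:
            scaled[ch] = pts[ch] * c
        a = quantify(pts, std)
        b = quantify(scaled, std)
        assert b["sr_ugg"].to_numpy() == pytest.approx(a["sr_ugg"].to_numpy(), rel=1e-12)

    def test_nonpositive_ca_flagged_not_raised(self):
        std = StandardSeries(_standards_df(), BLANK0)
        pts = _points()
        pts.loc[2, "ca"] = 0.0
        out = quantify(pts, std)
        assert out["invalid"].tolist() == [False, False, True, False, False]

    def test_blank_and_drift_order_commute_on_linear_fixtures(self):
        # both steps are linear maps when the blank is zero
        std = StandardSeries(_standards_df((1.0, 1.3)), BLANK0)
        pts = _points(sr=1234.0, mg=567.0, ca=8900.0)
        a = correct_drift(subtract_blank(pts, BLANK0), std, 0.7)
        b = subtract_blank(correct_drift(pts, std, 0.7), BLANK0)
        for ch in CHANNELS:
            assert np.abs(a[ch].to_numpy() - b[ch].to_numpy()).max() < 1e-9


class TestMolarRatio:
    def test_zero_sr_gives_zero(self):
        assert to_molar_ratio(0.0, 1000.0) == 0.0

    def test_equal_mass_concentrations(self):
        # sr == ca in ug/g -> ratio = (MW_Ca / MW_Sr) x 1e6
        expect = MW["ca"] / MW["sr"] * 1e6
        assert to_molar_ratio(500.0, 500.0) == pytest.approx(expect)

    def test_halving_ca_doubles_ratio(self):
        assert to_molar_ratio(10.0, 500.0) == pytest.approx(
            2 * to_molar_ratio(10.0, 1000.0)
        )

    def test_nonpositive_ca_rejected(self):
        with pytest.raises(ReductionError):
            to_molar_ratio(10.0, 0.0)


def _profile(values, step=5.0, mgca=400.0):
    d = np.arange(len(values)) * step
    return pd.DataFrame({
        "distance_um": d, "srca_umol_mol": values,
        "mgca_umol_mol": mgca, "invalid": False,
    })


class TestSummaries:
    def test_constant_profile(self):
        p = _profile([400.0] * 41)  # 0..200 um
        s = summarize(p, "f1")
        assert s.core_srca == pytest.approx(400.0)
        assert s.edge_srca == pytest.approx(400.0)
        assert not s.vaterite

    def test_step_profile_core_is_weighted_window_mean(self):
        d = np.arange(0.0, 305.0, 5.0)
        vals = np.where(d < 125.0, 600.0, 300.0)
        s = summarize(_profile(vals), "f1")
        # core window [75, 125] closed: ten points at 600, one at 300
        assert s.core_srca == pytest.approx((10 * 600 + 300) / 11)
        assert 300.0 < s.core_srca < 600.0
        assert s.edge_srca == pytest.approx(300.0)

    def test_short_transect_rejected(self):
        with pytest.raises(SummaryError):
            summarize(_profile([400.0] * 29), "f1")  # 140 um

    def test_vateritic_core_flagged(self):
        p = _profile([100.0] * 61, mgca=1500.0)
        assert summarize(p, "f1").vaterite


class TestVateriteRule:
    @pytest.mark.parametrize(
        "srca,mgca,expect",
        [
            (100.0, 1500.0, True),   # both conditions met
            (100.0, 500.0, False),   # combination required
            (400.0, 1500.0, False),
            (150.0, 1000.0, False),  # strict boundary
            (149.9, 1000.1, True),
        ],
    )
    def test_combination_rule(self, srca, mgca, expect):
        assert flag_vaterite(srca, mgca) is expect

    def test_negative_ratio_rejected(self):
        with pytest.raises(ReductionError):
            flag_vaterite(-1.0, 500.0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(c=st.floats(min_value=0.01, max_value=100.0))
def test_full_reduction_scale_invariance(c):
    """Multiplying all raw channels by c>0 leaves ratio outputs unchanged."""
    std_df = _standards_df((1.0, 1.1))
    blanks = pd.DataFrame({"channel": list(CHANNELS), "mean": 0.0, "sd": 1.0})
    std = StandardSeries(std_df, BLANK0)
    raw = _points(sr=900.0, mg=450.0, ca=50_000.0, n=61)
    scaled = raw.copy()
    for ch in CHANNELS:
        scaled[ch] = raw[ch] * c
    a = reduce_transect(raw, blanks, std, 0.5)
    b = reduce_transect(scaled, blanks, std, 0.5)
    assert b["srca_umol_mol"].to_numpy() == pytest.approx(
        a["srca_umol_mol"].to_numpy(), rel=1e-12
    )
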
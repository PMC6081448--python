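"""Bench-assay calculators against hand and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungquant.assays import (
    CholesterolPanel,
    EffluxCounts,
    bal_turbidity,
    chol_pl_ratio,
    efflux_percent,
    esterified_cholesterol,
    qpcr_efficiency,
    relative_expression,
)


class TestEfflux:
    @pytest.mark.parametrize(
        "media, cells, expected", [(2500, 7500, 25.0), (0, 10, 0.0), (10, 0, 100.0)]
    )
    def test_hand_values(self, media, cells, expected):
        assert efflux_percent(EffluxCounts(media, cells)) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            EffluxCounts(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            EffluxCounts(-1, 5)

    @settings(max_examples=100, derandomize=True)
    @given(
        media=st.floats(0, 1e7),
        cells=st.floats(0, 1e7),
        k=st.floats(1e-3, 1e3),
    )
    def test_bounded_and_scale_invariant(self, media, cells, k):
        if media == 0 and cells == 0:
            return
        p = efflux_percent(EffluxCounts(media, cells))
        assert 0.0 <= p <= 100.0
        p_scaled = efflux_percent(EffluxCounts(media * k, cells * k))
        assert p_scaled == pytest.approx(p, rel=1e-9, abs=1e-9)


class TestCholesterol:
    def test_esterified_is_total_minus_free(self):
        assert esterified_cholesterol(CholesterolPanel(30.0, 12.0)) == 18.0
        assert esterified_cholesterol(CholesterolPanel(7.0, 7.0)) == 0.0

    def test_free_exceeding_total_rejected_not_clamped(self):
        with pytest.raises(ValueError, match="inconsistency"):
            CholesterolPanel(10.0, 11.0)

    @settings(max_examples=100, derandomize=True)
    @given(total=st.floats(0, 1e4), free_frac=st.floats(0, 1))
    def test_conservation(self, total, free_frac):
        free = total * free_frac
        panel = CholesterolPanel(total, free)
        assert esterified_cholesterol(panel) + free == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_ratio(self):
        assert chol_pl_ratio(CholesterolPanel(8.0, 2.0, phospholipid=4.0)) == 2.0

    def test_ratio_homogeneous_under_rescaling(self):
        a = chol_pl_ratio(CholesterolPanel(8.0, 2.0, phospholipid=4.0))
        b = chol_pl_ratio(CholesterolPanel(80.0, 20.0, phospholipid=40.0))
        assert a == pytest.approx(b)

    def test_zero_phospholipid_rejected(self):
        with pytest.raises(ValueError, match="phospholipid"):
            chol_pl_ratio(CholesterolPanel(8.0, 2.0, phospholipid=0.0))


class TestTurbidity:
    def test_quarter_dilution(self):
        # 250 µl sample into 750 µl buffer: dilution factor 4
        assert bal_turbidity(0.35, 250.0, 750.0) == pytest.approx(1.4)

    def test_no_diluent_is_identity(self):
        assert bal_turbidity(0.8, 100.0, 0.0) == pytest.approx(0.8)

    def test_zero_od_stays_zero(self):
        assert bal_turbidity(0.0, 250.0, 750.0) == 0.0

    def test_nonpositive_sample_volume_rejected(self):
        with pytest.raises(ValueError):
            bal_turbidity(0.5, 0.0, 750.0)


class TestQpcr:
    def test_perfect_doubling_curve(self):
        """Slope −log2(10)⁻¹... a −3.3219 slope must give E = 2.000."""
        logs = np.array([0.0, 1.0, 2.0, 3.0])
        cq = 30.0 - 3.321928 * logs
        assert qpcr_efficiency(logs, cq) == pytest.approx(2.0, abs=1e-3)

    def test_shallower_slope_means_lower_efficiency(self):
        logs = np.array([0.0, 1.0, 2.0, 3.0])
        e = qpcr_efficiency(logs, 30.0 - 3.6 * logs)
        assert e < 2.0

    def test_short_series_rejected(self):
        logs = np.array([0.0, 0.7, 1.4, 2.0])
        with pytest.raises(ValueError, match="3"):
            qpcr_efficiency(logs, 30.0 - 3.3 * logs)

    def test_identity_for_calibrator(self):
        assert relative_expression(2.0, 2.0, 25.0, 25.0, 20.0, 20.0) == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        assert relative_expression(2.0, 2.0, 24.0, 25.0, 20.0, 20.0) == pytest.approx(2.0)

    def test_ddcq_equals_pfaffl_at_e2(self):
        args = (2.0, 2.0, 23.5, 25.0, 19.0, 20.5)
        assert relative_expression(*args, method="ddcq") == pytest.approx(
            relative_expression(*args, method="pfaffl")
        )

    def test_against_standard_curve_backcalculation(self):
        """Oracle: fold change must equal the ratio of input amounts
        back-calculated from the standard curves of both genes."""
        rng = np.random.default_rng(3)
        slope_t, icept_t = -3.45, 31.0
        slope_r, icept_r = -3.30, 28.0
        logs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        e_t = qpcr_efficiency(logs, icept_t + slope_t * logs)
        e_r = qpcr_efficiency(logs, icept_r + slope_r * logs)

        amounts = {"sample": (5.0, 2.0), "calib": (1.5, 2.5)}  # (target, ref) inputs
        cq = {
            name: (
                icept_t + slope_t * np.log10(t_amt),
                icept_r + slope_r * np.log10(r_amt),
            )
            for name, (t_amt, r_amt) in amounts.items()
        }
        fold = relative_expression(
            e_t, e_r, cq["sample"][0], cq["calib"][0], cq["sample"][1], cq["calib"][1]
        )
        brute = (amounts["sample"][0] / amounts["calib"][0]) / (
            amounts["sample"][1] / amounts["calib"][1]
        )
        assert fold == pytest.approx(brute, rel=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(
        d1=st.floats(-3, 3),
        d2=st.floats(-3, 3),
        r1=st.floats(-2, 2),
        r2=st.floats(-2, 2),
    )
    def test_multiplicative_under_composed_shifts(self, d1, d2, r1, r2):
        """Composing two ΔCq shifts multiplies the fold changes."""
        base_t, base_r = 25.0, 20.0
        f12 = relative_expression(2.0, 1.9, base_t - d1 - d2, base_t, base_r - r1 - r2, base_r)
        f1 = relative_expression(2.0, 1.9, base_t - d1, base_t, base_r - r1, base_r)
        f2 = relative_expression(2.0, 1.9, base_t - d1 - d2, base_t - d1, base_r - r1 - r2, base_r - r1)
        assert f12 == pytest.approx(f1 * f2, rel=1e-9)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            relative_expression(2.5, 2.0, 25, 25, 20, 20)
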
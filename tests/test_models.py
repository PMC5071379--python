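"""Closed-form bias/SD predictions of the two center-estimation models."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from fieldcenter.models import (
    BisectionParams,
    Feedback,
    ForceField,
    ProbeMode,
    PsychophysicalLaw,
    StiffnessProbe,
    bisection_bias,
    bisection_sd,
    perceived_force,
    prediction_band,
    stiffness_bilateral_bias,
    stiffness_center_estimate,
    stiffness_unilateral_bias,
)

stiffness_values = st.sampled_from([4.0, 8.0, 16.0])
thresholds = st.floats(0.01, 0.3)


class TestPerceivedForce:
    @pytest.mark.parametrize("law, F, expected", [
        ((1.0, 0.8, 0.1), 0.1, 0.0),        # at threshold: nothing perceived
        ((1.0, 1.0, 0.0), 0.37, 0.37),      # identity transducer
        ((2.0, 0.5, 0.1), 0.35, 1.0),       # 2*(0.25)**0.5
        ((1.0, 0.8, 0.1), 0.05, 0.0),       # below threshold
    ])
    def test_values(self, law, F, expected):
        alpha, beta, F_th = law
        got = perceived_force(PsychophysicalLaw(alpha, beta, F_th), F)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            perceived_force(PsychophysicalLaw(), -0.1)

    @given(beta=st.floats(0.3, 1.5), F_th=st.floats(0.0, 0.2),
           F1=st.floats(0.0, 1.0), F2=st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_physical_force(self, beta, F_th, F1, F2):
        law = PsychophysicalLaw(beta=beta, F_th=F_th)
        lo, hi = sorted([F1, F2])
        assert perceived_force(law, lo) <= perceived_force(law, hi)


class TestBisectionBias:
    @pytest.mark.parametrize("field, F_th, expected", [
        (ForceField(8, 8), 0.085, 0.0),            # symmetric field cancels
        (ForceField(16, 4), 0.1, 0.009375),        # 0.5*(-0.1/16 + 0.1/4)
        (ForceField(0, 8), 0.12, 0.015),           # unilateral right: F_th/K
        (ForceField(8, 0), 0.12, -0.015),          # unilateral left mirrors
    ])
    def test_values(self, field, F_th, expected):
        got = bisection_bias(field, BisectionParams(F_th=F_th))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_stiffness_field_rejected(self):
        with pytest.raises(ValueError):
            ForceField(0, 0)

    @given(kl=stiffness_values, kr=stiffness_values, F_th=thresholds)
    @settings(max_examples=50, derandomize=True)
    def test_mirroring_negates_bias_preserves_sd(self, kl, kr, F_th):
        p = BisectionParams(F_th=F_th, sigma_Fth=0.05, sigma_P_fp=0.01)
        f = ForceField(kl, kr)
        m = f.mirrored()
        assert bisection_bias(m, p) == pytest.approx(-bisection_bias(f, p))
        assert bisection_sd(m, p, Feedback.PRESENT) == pytest.approx(
            bisection_sd(f, p, Feedback.PRESENT))

    @given(F1=thresholds, F2=thresholds, K1=st.floats(2.0, 30.0),
           K2=st.floats(2.0, 30.0))
    @settings(max_examples=50, derandomize=True)
    def test_unilateral_bias_monotone(self, F1, F2, K1, K2):
        # weaker springs and higher thresholds both push the endpoint out
        lo_F, hi_F = sorted([F1, F2])
        lo_K, hi_K = sorted([K1, K2])
        bias = lambda F, K: bisection_bias(ForceField(0, K),
                                           BisectionParams(F_th=F))
        assert bias(lo_F, lo_K) <= bias(hi_F, lo_K)
        assert bias(lo_F, hi_K) <= bias(lo_F, lo_K)


class TestBisectionSD:
    def test_no_noise_no_spread(self):
        p = BisectionParams(F_th=0.1)
        assert bisection_sd(ForceField(8, 8), p, Feedback.PRESENT) == 0.0

    def test_symmetric_field_value(self):
        p = BisectionParams(F_th=0.085, sigma_Fth=0.052, sigma_P_fp=0.0093)
        got = bisection_sd(ForceField(8, 8), p, Feedback.PRESENT)
        expected = math.sqrt(0.25 * (2 * 0.052**2 / 64 + 2 * 0.0093**2))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.008023, abs=1e-6)

    def test_unilateral_value(self):
        p = BisectionParams.unilateral(0.1, sigma_F=0.062, sigma_P=0.0051)
        got = bisection_sd(ForceField(0, 8), p)
        assert got == pytest.approx(math.sqrt(0.062**2 / 64 + 0.0051**2),
                                    rel=1e-12)

    def test_feedback_switch_selects_positional_noise(self):
        p = BisectionParams(F_th=0.085, sigma_Fth=0.05,
                            sigma_P_fp=0.005, sigma_P_fa=0.02)
        f = ForceField(16, 4)
        assert bisection_sd(f, p, Feedback.PRESENT) < bisection_sd(
            f, p, Feedback.ABSENT)

    @given(kl=st.floats(2.0, 30.0), kr=st.floats(2.0, 30.0),
           scale=st.floats(1.0, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_nonincreasing_in_stiffness(self, kl, kr, scale):
        p = BisectionParams(F_th=0.085, sigma_Fth=0.05, sigma_P_fp=0.01)
        base = bisection_sd(ForceField(kl, kr), p, Feedback.PRESENT)
        stiffer = bisection_sd(ForceField(kl * scale, kr), p, Feedback.PRESENT)
        assert stiffer <= base + 1e-15

    def test_bilateral_needs_feedback_condition(self):
        with pytest.raises(ValueError):
            bisection_sd(ForceField(8, 8), BisectionParams(F_th=0.1),
                         Feedback.NA)


class TestStiffnessModel:
    @pytest.mark.parametrize("beta, x, x0, expected", [
        (0.8, 0.0125, 0.0125, 0.0125),   # zero probe depth
        (1.0, 0.05, 0.0125, 0.0125),     # beta=1 lands on the threshold
        (0.8, 0.05, 0.0125, 0.003125),   # 0.05 - 0.0375/0.8
    ])
    def test_center_estimate(self, beta, x, x0, expected):
        law = PsychophysicalLaw(beta=beta, F_th=0.1)
        assert stiffness_center_estimate(law, x, x0) == pytest.approx(
            expected, abs=1e-12)

    def test_subthreshold_probe_rejected(self):
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        with pytest.raises(ValueError):
            stiffness_center_estimate(law, 0.005, 0.0125)

    @given(depth1=st.floats(0.001, 0.05), depth2=st.floats(0.001, 0.05))
    @settings(max_examples=50, derandomize=True)
    def test_deeper_probes_overshoot_further(self, depth1, depth2):
        # with beta < 1 the extrapolated edge recedes as the probe deepens
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        x0 = 0.0125
        lo, hi = sorted([depth1, depth2])
        est_lo = stiffness_center_estimate(law, x0 + lo, x0)
        est_hi = stiffness_center_estimate(law, x0 + hi, x0)
        assert est_hi <= est_lo

    def test_bilateral_symmetric_is_unbiased(self):
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        got = stiffness_bilateral_bias(law, ForceField(8, 8),
                                       StiffnessProbe(probe_force=0.3))
        assert got == pytest.approx(0.0, abs=1e-15)

    def test_bilateral_equal_force_value(self):
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        got = stiffness_bilateral_bias(law, ForceField(16, 4),
                                       StiffnessProbe(probe_force=0.32))
        assert got == pytest.approx(0.00421875, abs=1e-12)

    @given(F_th=st.floats(0.05, 0.1), probe=st.floats(0.11, 0.9),
           kl=stiffness_values, kr=stiffness_values)
    @settings(max_examples=100, derandomize=True)
    def test_beta_one_collapses_to_bisection(self, F_th, probe, kl, kr):
        law = PsychophysicalLaw(beta=1.0, F_th=F_th)
        field = ForceField(kl, kr)
        got = stiffness_bilateral_bias(law, field,
                                       StiffnessProbe(probe_force=probe))
        want = bisection_bias(field, BisectionParams(F_th=F_th))
        assert got == pytest.approx(want, abs=1e-12)

    def test_stiffness_bias_below_bisection_for_deep_probes(self):
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        field = ForceField(16, 4)
        bis = bisection_bias(field, BisectionParams(F_th=0.1))
        got = stiffness_bilateral_bias(law, field,
                                       StiffnessProbe(probe_force=0.32))
        assert 0 < got < bis

    def test_probe_at_threshold_rejected(self):
        law = PsychophysicalLaw(beta=0.8, F_th=0.1)
        with pytest.raises(ValueError):
            stiffness_bilateral_bias(law, ForceField(16, 4),
                                     StiffnessProbe(probe_force=0.1))
        with pytest.raises(ValueError):
            stiffness_unilateral_bias(law, ForceField(0, 8), 0.05)


class TestPredictionBand:
    @pytest.mark.parametrize("field, expected", [
        (ForceField(0, 4), (0.0125, 0.025)),
        (ForceField(8, 8), (0.0, 0.0)),
        (ForceField(16, 4), (0.0046875, 0.009375)),
    ])
    def test_bisection_band(self, field, expected):
        got = prediction_band(field, (0.05, 0.1), model="bisection")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            prediction_band(ForceField(16, 4), ())

    def test_stiffness_band_sits_below_bisection_band(self):
        field = ForceField(16, 4)
        bis = prediction_band(field, (0.05, 0.1), model="bisection")
        stf = prediction_band(field, (0.05, 0.1), model="stiffness")
        assert stf[1] <= bis[1]
        assert stf[0] < bis[0]  # deep probes reach toward zero

    def test_stiffness_band_unilateral(self):
        field = ForceField(0, 8)
        bis = prediction_band(field, (0.05, 0.1), model="bisection")
        stf = prediction_band(field, (0.05, 0.1), model="stiffness")
        assert stf[1] <= bis[1] + 1e-12
        assert stf[0] < bis[0]
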
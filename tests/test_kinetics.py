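"""Fermi and distributed-parameter impulse responses and forward models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrperf.curves import ConcentrationCurve
from cmrperf.kinetics import (
    DPParams,
    FermiParams,
    dp_forward,
    dp_impulse_numeric,
    dp_transfer,
    fermi_forward,
    fermi_response,
    microvascular_profile,
)


class TestFermiResponse:
    def test_half_height_at_shoulder(self):
        p = FermiParams(mbf=1.0, tau0=4.0, k_decay=0.3)
        assert fermi_response(4.0, p) == 0.5

    def test_zero_decay_rate_is_flat_half(self):
        p = FermiParams(mbf=1.0, tau0=4.0, k_decay=0.0)
        assert np.allclose(fermi_response(np.linspace(0, 100, 11), p), 0.5)

    def test_tail_vanishes(self):
        p = FermiParams(mbf=1.0, tau0=4.0, k_decay=0.5)
        assert fermi_response(4.0 + 10.0 / 0.5, p) < 1e-4

    def test_monotone_non_increasing(self):
        p = FermiParams(mbf=1.0, tau0=3.0, k_decay=0.25)
        r = fermi_response(np.linspace(0, 60, 200), p)
        assert np.all(np.diff(r) <= 0)


class TestDPTransfer:
    def test_dc_gain_is_overall_transit_time(self, dp_params):
        assert dp_transfer(0.0, dp_params) == pytest.approx(dp_params.t_overall)

    def test_vanishing_interstitial_transit_reduces_to_plug_flow(self):
        p = DPParams(mbf=1.0, t_overall=10.0, t_cap=5.0, t_int=1e-9)
        s = 0.3 + 0.2j
        plug = (1.0 - np.exp(-s * p.t_overall)) / s
        assert dp_transfer(s, p) == pytest.approx(plug, rel=1e-6)

    def test_high_frequency_limit_is_capillary_transit(self, dp_params):
        s = 1e6 + 0j
        expected = (1.0 - np.exp(-s * dp_params.t_cap)) / s
        assert dp_transfer(s, dp_params) == pytest.approx(expected, rel=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mbf=st.floats(0.5, 6.0),
        t_overall=st.floats(3.0, 60.0),
        frac=st.floats(0.05, 1.0),
        t_int=st.floats(1.0, 100.0),
    )
    def test_dc_gain_property(self, mbf, t_overall, frac, t_int):
        p = DPParams(mbf=mbf, t_overall=t_overall, t_cap=frac * t_overall, t_int=t_int)
        assert dp_transfer(0.0, p) == pytest.approx(p.t_overall)


class TestDPImpulse:
    def test_area_equals_overall_transit_time(self, dp_params):
        dt = 0.25
        t = np.arange(0.0, 2.0 * (dp_params.t_overall + 5 * dp_params.t_int), dt)
        r = dp_impulse_numeric(dp_params, t)
        assert np.sum(r) * dt == pytest.approx(dp_params.t_overall, rel=0.01)

    def test_plug_flow_limit_is_unit_box(self):
        p = DPParams(mbf=1.0, t_overall=10.0, t_cap=6.0, t_int=1e-3)
        dt = 0.05
        t = np.arange(0.0, 40.0, dt)
        r = dp_impulse_numeric(p, t)
        inside = (t > 1.0) & (t < 9.0)
        outside = t > 12.0
        assert np.allclose(r[inside], 1.0, atol=1e-3)
        assert np.max(np.abs(r[outside])) < 1e-3
        assert np.sum(r) * dt == pytest.approx(10.0, rel=1e-3)

    def test_initial_value_near_unity(self, dp_params):
        t = np.arange(0.0, 300.0, 0.25)
        r = dp_impulse_numeric(dp_params, t)
        assert r[0] == pytest.approx(1.0, abs=0.1)

    def test_window_shorter_than_response_rejected(self, dp_params):
        t = np.arange(0.0, 10.0, 0.5)
        with pytest.raises(ValueError, match="window too short"):
            dp_impulse_numeric(dp_params, t)


class TestForwardModels:
    def test_fermi_impulse_input_returns_scaled_response(self):
        p = FermiParams(mbf=3.0, tau0=4.0, k_decay=0.3)
        dt = 1.0
        t = np.arange(40.0)
        impulse = np.zeros(40)
        impulse[0] = 1.0 / dt  # unit mass in mM*s
        aif = ConcentrationCurve(times=t, values=impulse)
        out = fermi_forward(aif, p)
        assert np.allclose(out.values, (p.mbf / 60.0) * fermi_response(t, p))

    def test_fermi_matches_brute_force_convolution(self, gaussian_aif):
        p = FermiParams(mbf=3.5, tau0=4.0, k_decay=0.3)
        out = fermi_forward(gaussian_aif, p).values
        n = len(gaussian_aif)
        dt = gaussian_aif.dt
        r = fermi_response(gaussian_aif.times, p)
        brute = np.array(
            [sum(r[m] * gaussian_aif.values[j - m] for m in range(j + 1)) for j in range(n)]
        ) * dt * p.mbf / 60.0
        assert np.max(np.abs(out - brute)) <= 1e-8 * np.max(np.abs(out))

    def test_dp_matches_brute_force_convolution_with_numeric_impulse(self, dp_params):
        # fine grid; the numeric impulse samples R at cell midpoints, so the
        # brute-force sum approximates the convolution at t + dt/2 and is
        # compared against the midpoint-interpolated spectral result
        dt = 0.05
        t = np.arange(0.0, 120.0, dt)
        aif_v = 4.0 * np.exp(-0.5 * ((t - 15.0) / 4.0) ** 2)
        aif = ConcentrationCurve(times=t, values=aif_v)
        out = dp_forward(aif, dp_params).values
        r = dp_impulse_numeric(
            dp_params, np.arange(0.0, 2.0 * (dp_params.t_overall + 5 * dp_params.t_int), dt)
        )
        brute = np.convolve(aif_v, r[: t.size])[: t.size] * dt * dp_params.mbf / 60.0
        midpoint = 0.5 * (out[:-1] + out[1:])
        err = np.max(np.abs(midpoint - brute[:-1])) / np.max(np.abs(out))
        assert err < 1e-3

    def test_dp_impulse_input_consistent_with_numeric_residue(self, dp_params):
        dt = 0.25
        n = 2048
        t = dt * np.arange(n)
        impulse = np.zeros(n)
        impulse[0] = 1.0 / dt
        aif = ConcentrationCurve(times=t, values=impulse)
        out = dp_forward(aif, dp_params).values
        # spectral convolution with a discrete delta reproduces the inverse
        # FFT of the transfer function sampled on the same grid (no shift)
        r_mid = dp_impulse_numeric(dp_params, t)
        area_out = np.sum(out) * dt
        assert area_out == pytest.approx(
            dp_params.mbf / 60.0 * dp_params.t_overall, rel=3e-3
        )
        assert np.sum(r_mid) * dt == pytest.approx(dp_params.t_overall, rel=3e-3)

    def test_dp_plug_flow_impulse_is_scaled_box(self):
        p = DPParams(mbf=3.0, t_overall=10.0, t_cap=6.0, t_int=1e-3)
        dt = 0.1
        n = 1024
        t = dt * np.arange(n)
        impulse = np.zeros(n)
        impulse[0] = 1.0 / dt
        out = dp_forward(ConcentrationCurve(times=t, values=impulse), p).values
        inside = (t > 1.0) & (t < 9.0)
        assert np.allclose(out[inside], p.mbf / 60.0, rtol=1e-2)
        assert np.max(np.abs(out[t > 13.0])) < 1e-3 * p.mbf / 60.0

    @pytest.mark.parametrize("forward,params", [
        (fermi_forward, FermiParams(mbf=2.0, tau0=3.0, k_decay=0.2)),
        (dp_forward, DPParams(mbf=2.0, t_overall=12.0, t_cap=3.0, t_int=14.0)),
    ])
    def test_linearity_in_flow_and_input(self, gaussian_aif, forward, params):
        out = forward(gaussian_aif, params).values
        doubled = type(params)(**{**params.__dict__, "mbf": 2 * params.mbf})
        assert np.allclose(forward(gaussian_aif, doubled).values, 2 * out, atol=1e-12)
        half_aif = gaussian_aif.with_values(0.5 * gaussian_aif.values)
        assert np.allclose(forward(half_aif, params).values, 0.5 * out, atol=1e-12)

    @pytest.mark.parametrize("forward,params", [
        (fermi_forward, FermiParams(mbf=2.0, tau0=3.0, k_decay=0.2)),
        (dp_forward, DPParams(mbf=2.0, t_overall=12.0, t_cap=3.0, t_int=14.0)),
    ])
    def test_time_shift_equivariance(self, forward, params):
        t = np.arange(128.0)
        base = np.zeros(128)
        base[10:40] = np.hanning(30)
        shifted = np.roll(base, 7)
        out_base = forward(ConcentrationCurve(times=t, values=base), params).values
        out_shift = forward(ConcentrationCurve(times=t, values=shifted), params).values
        assert np.allclose(out_shift[7:], out_base[:-7], atol=1e-8)

    def test_non_uniform_sampling_rejected(self, dp_params):
        t = np.array([0.0, 1.0, 2.5, 3.0, 4.0])
        aif = ConcentrationCurve(times=t, values=np.ones(5))
        with pytest.raises(ValueError, match="uniform"):
            dp_forward(aif, dp_params)


class TestMicrovascularProfile:
    def test_haematocrit_converts_blood_to_plasma_flow(self):
        p = DPParams(mbf=1.0, t_overall=12.0, t_cap=3.0, t_int=14.0)
        prof = microvascular_profile(p, hct=0.45)
        assert prof.mpf == pytest.approx(0.55)

    def test_extraction_half_at_ln2_ratio(self):
        # choose t_int so PS/MPF = ln 2 exactly
        mbf, t_overall, t_cap, hct = 2.0, 12.0, 3.0, 0.45
        mpf = mbf * (1 - hct)
        t_int = mpf * (t_overall - t_cap) / (mpf * np.log(2.0))
        prof = microvascular_profile(
            DPParams(mbf=mbf, t_overall=t_overall, t_cap=t_cap, t_int=t_int), hct=hct
        )
        assert prof.extraction == pytest.approx(0.5, rel=1e-12)

    def test_no_interstitial_exchange_when_transits_equal(self):
        p = DPParams(mbf=2.0, t_overall=5.0, t_cap=5.0, t_int=10.0)
        prof = microvascular_profile(p, hct=0.45)
        assert prof.ve == 0.0
        assert prof.ps == 0.0
        assert prof.extraction == 0.0

    def test_volume_additivity_under_blood_flow_convention(self, dp_params):
        prof = microvascular_profile(dp_params, hct=0.45, convention="mbf")
        assert prof.vd == pytest.approx(prof.vb + prof.ve, abs=1e-12)

    def test_volumes_in_physiological_range(self, dp_params):
        prof = microvascular_profile(dp_params, hct=0.45)
        assert 0 < prof.vb < 0.3
        assert prof.vd >= prof.vb

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ps_scale=st.floats(0.1, 5.0),
        mbf=st.floats(0.5, 6.0),
    )
    def test_extraction_increases_with_permeability(self, ps_scale, mbf):
        t_overall, t_cap = 20.0, 4.0
        base = microvascular_profile(
            DPParams(mbf=mbf, t_overall=t_overall, t_cap=t_cap, t_int=10.0 / ps_scale)
        )
        more = microvascular_profile(
            DPParams(mbf=mbf, t_overall=t_overall, t_cap=t_cap, t_int=10.0 / (2 * ps_scale))
        )
        assert more.ps > base.ps
        assert more.extraction > base.extraction
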
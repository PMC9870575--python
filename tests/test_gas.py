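"""Gas-phase exchange measurement: Haldane transformation, breath
integration, delay matching, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecmofick.gas import (
    ExhaustFractions,
    SweepGasSetting,
    Waveform,
    WindowedExchange,
    ecmo_exhaust_exchange,
    estimate_sidestream_delay,
    haldane_outlet_flow,
    integrate_breath_vco2,
    integrate_breath_vo2,
    window_average,
)


def brute_force_outlet_flow(air, n2_frac, f_o2, f_co2):
    """Oracle: solve the three-gas mole balance for the outlet flow by
    bisection instead of the closed form."""
    n2_in = air * n2_frac

    def resid(q):
        return q * (1.0 - f_o2 - f_co2) - n2_in

    lo, hi = 0.0, 1000.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestHaldane:
    @pytest.mark.parametrize(
        "air, f_o2, f_co2, expected",
        [
            (2.0, 0.55, 0.05, 1.58 / 0.40),
            (0.0, 0.55, 0.05, 0.0),
            (2.025, 0.57, 0.04, 2.025 * 0.79 / 0.39),
        ],
    )
    def test_known_values(self, air, f_o2, f_co2, expected):
        sweep = SweepGasSetting(air_inflow=air, o2_inflow=2.0)
        out = haldane_outlet_flow(sweep, ExhaustFractions(f_o2, f_co2))
        assert out == pytest.approx(expected, rel=1e-12)

    def test_small_nitrogen_fraction_rejected(self):
        sweep = SweepGasSetting(air_inflow=0.1, o2_inflow=4.0)
        with pytest.raises(ValueError, match="nitrogen fraction too small"):
            haldane_outlet_flow(sweep, ExhaustFractions(0.93, 0.03))

    @given(
        air=st.floats(0.1, 6.0),
        o2=st.floats(0.0, 6.0),
        f_o2=st.floats(0.0, 0.8),
        f_co2=st.floats(0.0, 0.1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_nitrogen_mass_balance_closes(self, air, o2, f_o2, f_co2):
        if 1.0 - f_o2 - f_co2 <= 0.05:
            return
        sweep = SweepGasSetting(air_inflow=air, o2_inflow=o2)
        exhaust = ExhaustFractions(f_o2, f_co2)
        q_out = haldane_outlet_flow(sweep, exhaust)
        assert q_out * (1.0 - f_o2 - f_co2) == pytest.approx(
            air * 0.79, rel=1e-12, abs=1e-12
        )

    def test_matches_brute_force_mole_balance(self):
        for f_o2 in (0.3, 0.5, 0.6):
            for f_co2 in (0.01, 0.04, 0.08):
                sweep = SweepGasSetting(air_inflow=2.025, o2_inflow=1.975)
                got = haldane_outlet_flow(sweep, ExhaustFractions(f_o2, f_co2))
                want = brute_force_outlet_flow(2.025, 0.79, f_o2, f_co2)
                assert got == pytest.approx(want, rel=1e-9)


class TestExhaustExchange:
    def test_hand_value_vco2(self):
        sweep = SweepGasSetting(air_inflow=2.025, o2_inflow=1.975)
        exhaust = ExhaustFractions(0.57, 0.04)
        vo2, vco2 = ecmo_exhaust_exchange(sweep, exhaust)
        q_out = 2.025 * 0.79 / 0.39
        assert vco2 == pytest.approx(q_out * 0.04 * 1000.0, rel=1e-12)
        assert vco2 == pytest.approx(164.1, abs=0.1)

    def test_no_transfer_when_exhaust_equals_inlet(self):
        sweep = SweepGasSetting(air_inflow=2.0, o2_inflow=2.0)  # fd_o2 = 0.605
        vo2, vco2 = ecmo_exhaust_exchange(sweep, ExhaustFractions(sweep.fd_o2, 0.0))
        assert vo2 == pytest.approx(0.0, abs=1e-9)
        assert vco2 == 0.0

    def test_pass_through_air(self):
        sweep = SweepGasSetting(air_inflow=2.0, o2_inflow=0.0)
        vo2, vco2 = ecmo_exhaust_exchange(sweep, ExhaustFractions(0.21, 0.0))
        assert vo2 == pytest.approx(0.0, abs=1e-9)
        assert vco2 == 0.0

    def test_exact_against_constructed_transfer(self):
        # build exhaust fractions from a known (vo2, vco2) mole balance and
        # check the function recovers them
        sweep = SweepGasSetting(air_inflow=2.5, o2_inflow=1.5)
        total = sweep.total_inflow
        for vo2_true, vco2_true in [(100.0, 80.0), (250.0, 200.0), (30.0, 150.0)]:
            o2_out = sweep.o2_inflow_total - vo2_true / 1000.0
            co2_out = vco2_true / 1000.0
            n2_out = sweep.air_inflow * 0.79
            q_out = o2_out + co2_out + n2_out
            exhaust = ExhaustFractions(o2_out / q_out, co2_out / q_out)
            vo2, vco2 = ecmo_exhaust_exchange(sweep, exhaust)
            assert vo2 == pytest.approx(vo2_true, rel=1e-9)
            assert vco2 == pytest.approx(vco2_true, rel=1e-9)


def square_breaths(
    rate_hz=50.0,
    breath_rate=15.0,
    exp_frac=0.6,
    exp_flow=6.0,
    fco2_exp=0.05,
    fi_o2=0.21,
    fe_o2=0.16,
    duration=60.0,
):
    """Construct square-wave breath waveforms with a closed-form transport."""
    n = int(duration * rate_hz)
    samples_per_breath = int(round(rate_hz * 60.0 / breath_rate))
    exp_samples = int(round(exp_frac * samples_per_breath))
    exp_mask = (np.arange(n) % samples_per_breath) < exp_samples
    insp_flow = -exp_flow * exp_frac / (1.0 - exp_frac)  # balanced volumes
    flow = np.where(exp_mask, exp_flow, insp_flow)
    fco2 = np.where(exp_mask, fco2_exp, 0.0)
    fo2 = np.where(exp_mask, fe_o2, fi_o2)
    return (
        Waveform(0.0, rate_hz, flow),
        Waveform(0.0, rate_hz, fco2, is_fraction=True),
        Waveform(0.0, rate_hz, fo2, is_fraction=True),
        exp_mask,
    )


class TestBreathIntegration:
    def test_vco2_square_wave_closed_form(self):
        flow, fco2, _, exp_mask = square_breaths()
        # closed form: mean expiratory transport over the window
        expected = np.mean(np.where(exp_mask, 6.0 * 0.05, 0.0)) * 1000.0
        got = integrate_breath_vco2(flow, fco2)
        assert got == pytest.approx(expected, rel=0.01)

    def test_vco2_zero_fraction(self):
        flow, _, _, _ = square_breaths()
        zeros = Waveform(0.0, 50.0, np.zeros(flow.values.size), is_fraction=True)
        assert integrate_breath_vco2(flow, zeros) == 0.0

    def test_vco2_linear_in_flow_amplitude(self):
        flow, fco2, _, _ = square_breaths()
        doubled = Waveform(0.0, 50.0, 2.0 * flow.values)
        assert integrate_breath_vco2(doubled, fco2) == pytest.approx(
            2.0 * integrate_breath_vco2(flow, fco2), rel=1e-12
        )

    def test_vo2_no_extraction_is_zero(self):
        flow, _, _, _ = square_breaths()
        const = Waveform(0.0, 50.0, np.full(flow.values.size, 0.21),
                         is_fraction=True)
        # balanced tidal volumes: net O2 transport vanishes
        assert integrate_breath_vo2(flow, const) == pytest.approx(0.0, abs=1e-6)

    def test_vo2_closed_form_and_sign(self):
        flow, _, fo2, exp_mask = square_breaths(fi_o2=0.21, fe_o2=0.16)
        insp_flow = -6.0 * 0.6 / 0.4
        expected = -np.mean(
            np.where(exp_mask, 6.0 * 0.16, insp_flow * 0.21)
        ) * 1000.0
        got = integrate_breath_vo2(flow, fo2)
        assert got == pytest.approx(expected, rel=0.01)
        assert got > 0  # expired O2 below inspired -> positive uptake

    def test_window_shorter_than_one_breath(self):
        flow = Waveform(0.0, 50.0, np.full(25, 6.0))  # no inspiration at all
        fco2 = Waveform(0.0, 50.0, np.full(25, 0.05), is_fraction=True)
        with pytest.raises(ValueError, match="one breath"):
            integrate_breath_vco2(flow, fco2)

    def test_resampling_different_rates(self):
        flow, fco2, _, _ = square_breaths(rate_hz=100.0)
        ref = integrate_breath_vco2(flow, fco2)
        # CO2 channel at half the rate: recovered within the 2% resampling band
        low = Waveform(0.0, 50.0, fco2.values[::2], is_fraction=True)
        assert integrate_breath_vco2(flow, low) == pytest.approx(ref, rel=0.02)


class TestSidestreamDelay:
    def make_pair(self, shift_s, rate=50.0, noise_sd=0.0, seed=0):
        t = np.arange(int(30 * rate)) / rate
        co2 = 0.025 * (1 + np.sign(np.sin(2 * np.pi * t / 4.0)))
        o2_clean = 0.6 - 1.5 * co2
        lag = int(round(shift_s * rate))
        o2 = np.concatenate([np.full(lag, o2_clean[0]), o2_clean[: o2_clean.size - lag]])
        if noise_sd:
            rng = np.random.default_rng(seed)
            o2 = o2 + rng.normal(0.0, noise_sd, o2.size)
        return (
            Waveform(0.0, rate, co2, is_fraction=True),
            Waveform(0.0, rate, np.clip(o2, 0, 1), is_fraction=True),
        )

    @pytest.mark.parametrize("shift", [0.0, 0.24, 1.5])
    def test_constructed_shift_recovered(self, shift):
        co2, o2 = self.make_pair(shift)
        assert estimate_sidestream_delay(co2, o2) == pytest.approx(shift, abs=1e-9)

    def test_noisy_shift_within_one_sample(self):
        # additive noise at 10% of the modulation amplitude, fixed seed
        co2, o2 = self.make_pair(0.8, noise_sd=0.1 * 0.075, seed=42)
        assert estimate_sidestream_delay(co2, o2) == pytest.approx(0.8, abs=1.0 / 50.0)

    def test_flat_signal_rejected(self):
        rate = 50.0
        flat = Waveform(0.0, rate, np.full(500, 0.04), is_fraction=True)
        mod = Waveform(0.0, rate, 0.04 + 0.01 * np.sin(np.arange(500) / 10.0),
                       is_fraction=True)
        with pytest.raises(ValueError, match="no respiratory modulation"):
            estimate_sidestream_delay(flat, mod)


class TestWindowAverage:
    def test_constant_series(self):
        out = window_average(np.arange(0, 180, 4.0), np.full(45, 120.0), 180.0)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(120.0)

    def test_two_breaths(self):
        out = window_average([0.0, 10.0], [100.0, 200.0], 180.0)
        assert out[0][1] == pytest.approx(150.0)

    def test_drifting_series_matches_brute_force(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(2.0, 5.0, 200))
        v = 150.0 + 0.1 * t + rng.normal(0, 5, t.size)
        out = window_average(t, v, 180.0)
        for w0, mean, n in out:
            mask = (t >= w0) & (t < w0 + 180.0)
            if n:
                assert mean == pytest.approx(v[mask].mean(), rel=1e-12)
            else:
                assert np.isnan(mean)

    def test_empty_window_flagged_missing(self):
        out = window_average([0.0, 400.0], [100.0, 200.0], 180.0)
        starts = [w for w, _, _ in out]
        assert starts == [0.0, 180.0, 360.0]
        assert np.isnan(out[1][1]) and out[1][2] == 0


class TestTypes:
    def test_sweep_blend_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SweepGasSetting(air_inflow=2.0, o2_inflow=2.0, fd_o2=0.3)
        s = SweepGasSetting(air_inflow=2.0, o2_inflow=2.0)
        assert s.fd_o2 == pytest.approx((0.21 * 2 + 2) / 4)

    def test_exhaust_invariant(self):
        with pytest.raises(ValueError):
            ExhaustFractions(0.7, 0.4)

    def test_windowed_exchange_magnitudes(self):
        with pytest.raises(ValueError, match="magnitude"):
            WindowedExchange(0.0, vo2_lung=-5.0, vco2_lung=1.0,
                             vo2_ecmo=1.0, vco2_ecmo=1.0)

    def test_waveform_validation(self):
        with pytest.raises(ValueError):
            Waveform(0.0, 0.0, np.zeros(5))
        with pytest.raises(ValueError):
            Waveform(0.0, 50.0, np.array([0.1, np.nan]))
        with pytest.raises(ValueError):
            Waveform(0.0, 50.0, np.array([0.5, 1.5]), is_fraction=True)
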
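"""Fick engine: flow from content differences / exchange ratios, V/Q
normalization, per-window estimation, outlier filtering."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ecmofick.blood import BloodGasSample
from ecmofick.fick import (
    ContentDifference,
    FlowEstimate,
    Method,
    NormalizationParams,
    estimate_all_methods,
    filter_estimates,
    normalization_constant,
    normalize_vco2,
    qlung_from_contents,
    qlung_from_exchange,
    vq_lung,
)
from ecmofick.gas import WindowedExchange


class TestFlowFromContents:
    @pytest.mark.parametrize(
        "q_ecmo, pe, ao, la, expected",
        [
            (2000.0, 6.0, 5.0, 4.0, 2000.0),
            (4000.0, 8.0, 6.0, 2.0, 2000.0),
            (1500.0, 5.0, 5.0, 3.0, 0.0),
        ],
    )
    def test_known_values(self, q_ecmo, pe, ao, la, expected):
        assert qlung_from_contents(q_ecmo, pe, ao, la) == pytest.approx(expected)

    def test_degenerate_configuration(self):
        with pytest.raises(ValueError, match="degenerate"):
            qlung_from_contents(2000.0, 6.0, 4.0, 4.0)

    def test_mixed_gases_rejected(self):
        d1 = ContentDifference("V_PE", "O2", 6.0)
        d2 = ContentDifference("V_AO", "CO2", 5.0)
        d3 = ContentDifference("V_LA", "CO2", 4.0)
        with pytest.raises(ValueError, match="mix gases"):
            qlung_from_contents(2000.0, d1, d2, d3)


class TestFlowFromExchange:
    @pytest.mark.parametrize(
        "q_ecmo, lung, ecmo, expected",
        [
            (2000.0, 100.0, 100.0, 2000.0),
            (4000.0, 50.0, 200.0, 1000.0),
            (1000.0, 0.0, 200.0, 0.0),
        ],
    )
    def test_known_values(self, q_ecmo, lung, ecmo, expected):
        assert qlung_from_exchange(q_ecmo, lung, ecmo) == pytest.approx(expected)

    def test_zero_membrane_exchange(self):
        with pytest.raises(ValueError, match="no membrane exchange"):
            qlung_from_exchange(2000.0, 100.0, 0.0)

    @given(
        q_ecmo=st.floats(500.0, 5000.0),
        q_lung=st.floats(500.0, 5000.0),
        cv=st.floats(5.0, 11.0),
        c_la=st.floats(12.5, 18.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_equivalence_with_content_form(self, q_ecmo, q_lung, cv, c_la):
        """Exchange-ratio and content-ratio forms are rearrangements of
        the same mass balance under the equal-outflow premise (the
        content form is exactly degenerate at perfect equality, so the
        premise is perturbed infinitesimally)."""
        c_pe = c_la + 5e-7  # equal outflow contents up to a perturbation
        q_total = q_ecmo + q_lung
        c_ao = (q_lung * c_la + q_ecmo * c_pe) / q_total  # exact mix
        v_lung = q_lung * (c_la - cv) / 100.0
        v_ecmo = q_ecmo * (c_pe - cv) / 100.0
        via_exchange = qlung_from_exchange(q_ecmo, v_lung, v_ecmo)
        via_contents = qlung_from_contents(
            q_ecmo, cv - c_pe, cv - c_ao, cv - c_la
        )
        assert via_contents == pytest.approx(q_lung, rel=1e-6)
        assert via_exchange == pytest.approx(via_contents, rel=1e-6)

    def test_content_form_exact_for_any_mix(self):
        # with a common venous inflow and AO the exact flow-weighted mix,
        # the rearranged balance recovers the true flow even when the two
        # exchangers transfer different amounts per unit flow
        q_lung, q_ecmo, cv = 1800.0, 3200.0, 9.0
        c_la, c_pe = 13.0, 13.8
        c_ao = (q_lung * c_la + q_ecmo * c_pe) / (q_lung + q_ecmo)
        got = qlung_from_contents(q_ecmo, cv - c_pe, cv - c_ao, cv - c_la)
        assert got == pytest.approx(q_lung, rel=1e-9)

    def test_accepts_exchange_rates_container(self):
        from ecmofick.fick import ExchangeRates

        rates = ExchangeRates(vdot_lung=100.0, vdot_ecmo=100.0, gas="O2",
                              phase="blood")
        assert rates.vdot_total == 200.0
        assert qlung_from_exchange(2000.0, rates) == pytest.approx(2000.0)
        with pytest.raises(ValueError, match="magnitudes"):
            ExchangeRates(vdot_lung=-1.0, vdot_ecmo=1.0, gas="O2")
        with pytest.raises(ValueError, match="inconsistent"):
            ExchangeRates(vdot_lung=1.0, vdot_ecmo=1.0, gas="O2",
                          vdot_total=5.0)

    def test_monotonicity(self):
        base = qlung_from_exchange(2000.0, 100.0, 150.0)
        assert qlung_from_exchange(2000.0, 120.0, 150.0) > base
        assert qlung_from_exchange(2000.0, 100.0, 180.0) < base


class TestNormalization:
    def venous(self, ph=7.4):
        return BloodGasSample("RA", po2=45.0, pco2=45.0, so2=72.0, hb=9.0, ph=ph)

    def test_constant_limit_sigma_rt(self):
        params = normalization_constant(self.venous(ph=6.5), pk_prime=12.0)
        # Kc ~ 0 -> c -> sigma*R*T ~ 0.59
        assert params.c == pytest.approx(3.06e-5 * 62.36 * 310.15, rel=1e-3)
        assert params.c == pytest.approx(0.59, abs=0.01)

    @pytest.mark.parametrize("ph, expected", [(7.4, 12.42), (7.1, 6.52)])
    def test_hand_values(self, ph, expected):
        params = normalization_constant(self.venous(ph=ph))
        assert params.c == pytest.approx(expected, rel=0.01)
        assert params.k_c == pytest.approx(10.0 ** (ph - 6.1), rel=1e-12)

    def test_identity_at_unity_vq(self):
        params = NormalizationParams(c=12.0, vq_lung=1.0)
        assert normalize_vco2(200.0, params) == pytest.approx(200.0, rel=1e-15)

    def test_direct_arithmetic(self):
        params = NormalizationParams(c=12.0, vq_lung=2.0)
        assert normalize_vco2(200.0, params) == pytest.approx(200.0 * 14.0 / 26.0)

    @pytest.mark.parametrize("x", [0.25, 0.5, 2.0, 4.0])
    def test_inverse_model_identity(self, x):
        """Normalization exactly inverts the V/Q dependence of the model
        V(x) = V1 * x * (1+c) / (x+c)."""
        c, v1 = 12.4, 180.0
        vx = v1 * x * (1.0 + c) / (x + c)
        params = NormalizationParams(c=c, vq_lung=x)
        assert normalize_vco2(vx, params) == pytest.approx(v1, rel=1e-12)

    def test_invalid_vq(self):
        with pytest.raises(ValueError):
            NormalizationParams(c=12.0, vq_lung=-1.0)


class TestVQLung:
    @pytest.mark.parametrize(
        "fi, fe, ca, cv, expected",
        [
            (0.60, 0.55, 20.0, 15.0, 1.0),
            (0.60, 0.55, 15.0, 15.0, 0.0),
            (0.60, 0.58, 18.0, 14.0, 2.0),
        ],
    )
    def test_known_values(self, fi, fe, ca, cv, expected):
        assert vq_lung(fi, fe, ca, cv) == pytest.approx(expected)

    def test_no_extraction_rejected(self):
        with pytest.raises(ValueError, match="V/Q undefined"):
            vq_lung(0.6, 0.6, 20.0, 15.0)

    def test_positive_for_uptaking_lung(self):
        assert vq_lung(0.6, 0.56, 19.0, 14.0) > 0


class TestEstimateAllMethods:
    def test_noiseless_baseline_all_methods_agree(self, baseline_truth):
        from ecmofick import apply_measurement_noise

        rec = apply_measurement_noise(baseline_truth)
        ests = estimate_all_methods(
            rec.window, rec.samples, rec.q_ecmo, rec.q_lung_ref,
            rec.fi_o2, rec.fe_o2,
        )
        vals = [e.q_lung_calc for e in ests]
        assert len(ests) == 5
        for v in vals:
            assert v == pytest.approx(baseline_truth.q_lung, rel=0.01)

    def test_error_isolation_missing_ecmo_vco2(self, baseline_truth):
        from ecmofick import apply_measurement_noise

        rec = apply_measurement_noise(baseline_truth)
        window = WindowedExchange(
            0.0,
            vo2_lung=rec.window.vo2_lung,
            vco2_lung=rec.window.vco2_lung,
            vo2_ecmo=rec.window.vo2_ecmo,
            vco2_ecmo=0.0,
        )
        ests = {e.method: e for e in estimate_all_methods(
            window, rec.samples, rec.q_ecmo, rec.q_lung_ref,
            rec.fi_o2, rec.fe_o2)}
        assert math.isnan(ests[Method.VCO2_GAS].q_lung_calc)
        assert math.isnan(ests[Method.VCO2_GAS_NORM].q_lung_calc)
        assert math.isfinite(ests[Method.VO2_GAS].q_lung_calc)
        assert math.isfinite(ests[Method.VO2_BLOOD].q_lung_calc)

    def test_unity_vq_gas_equals_normalized(self, baseline_truth):
        # the default config runs the lung at V/Q = 1
        from ecmofick import apply_measurement_noise

        rec = apply_measurement_noise(baseline_truth)
        ests = {e.method: e.q_lung_calc for e in estimate_all_methods(
            rec.window, rec.samples, rec.q_ecmo, rec.q_lung_ref,
            rec.fi_o2, rec.fe_o2)}
        assert ests[Method.VCO2_GAS] == pytest.approx(
            ests[Method.VCO2_GAS_NORM], rel=1e-6
        )


class TestFilterEstimates:
    def make(self, q):
        return FlowEstimate(q_lung_calc=q, q_ecmo=2000.0, method=Method.VO2_BLOOD)

    def test_outlier_rule(self):
        ests = [self.make(-500.0), self.make(2000.0), self.make(12000.0)]
        kept = filter_estimates(ests)
        assert [e.q_lung_calc for e in kept] == [2000.0]

    def test_empty(self):
        assert filter_estimates([]) == []

    def test_all_valid_unchanged(self):
        ests = [self.make(q) for q in (100.0, 5000.0, 9999.0)]
        assert filter_estimates(ests) == ests

    def test_nan_removed(self):
        ests = [self.make(float("nan")), self.make(3000.0)]
        assert [e.q_lung_calc for e in filter_estimates(ests)] == [3000.0]
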
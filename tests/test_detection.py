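import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohear import (
    ComplexCoherence,
    GammatoneSpec,
    ModelParams,
    SensitivityBreakdown,
    StimulusSpec,
    ThresholdKernel,
    build_cspd,
    d_bin,
    d_mon,
    d_total,
    effective_snr,
    incoherence_threshold,
    ipd_discrimination_threshold,
    ipd_threshold_as_itd,
    make_experiment_spec,
    solve_threshold_snr,
)
from cohear.stimuli import TWO_PI

from conftest import broadband_noise, zero_ipd


def arctanh_ref(x):
    return 0.5 * math.log((1 + x) / (1 - x))


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rho_hat=1.0, sigma_bin=0.3),
            dict(rho_hat=0.9, sigma_bin=0.0),
            dict(rho_hat=0.9, sigma_bin=0.3, sigma_mon=-1.0),
            dict(rho_hat=0.9, sigma_bin=0.3, d_target=0.0),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


class TestBinauralSensitivity:
    def test_identical_stimuli_give_zero(self):
        g = ComplexCoherence(0.8 + 0.1j)
        assert d_bin(g, g, ModelParams(0.9, 0.19)) == 0.0

    def test_hand_evaluation_real_coherences(self):
        # gamma 1 vs 0.9, rho_hat 0.90: (arctanh(0.90) - arctanh(0.81)) / 0.19
        got = d_bin(
            ComplexCoherence(1.0 + 0j),
            ComplexCoherence(0.9 + 0j),
            ModelParams(0.90, 0.19),
        )
        expected = (arctanh_ref(0.90) - arctanh_ref(0.81)) / 0.19
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        rho_hat=st.floats(0.55, 0.998),
        sigma_bin=st.floats(0.02, 2.0),
        d_target=st.floats(0.1, 3.0),
    )
    def test_chord_length_identity(self, rho_hat, sigma_bin, d_target):
        # two unit-coherence stimuli whose mean IPDs differ by the
        # IPD-discrimination threshold produce exactly the criterion d'
        params = ModelParams(rho_hat, sigma_bin, d_target=d_target)
        if d_target * sigma_bin / (2 * arctanh_ref(rho_hat)) > 1:
            return
        dsig = ipd_discrimination_threshold(params)
        got = d_bin(
            ComplexCoherence(1.0 + 0j),
            ComplexCoherence(cmath.exp(1j * dsig)),
            params,
        )
        assert got == pytest.approx(d_target, rel=1e-9)


class TestEffectiveSnr:
    def test_narrowband_limit(self, default_filter):
        spec = StimulusSpec(
            zero_ipd, 1.0, 0.0, TWO_PI * 0.79, tone_present=True, snr=0.5
        )
        assert effective_snr(spec, default_filter) / 0.5 == pytest.approx(1.0, rel=0.01)

    def test_broadband_doubling_gains_3db(self, default_filter):
        vals = []
        for bw in (3200.0, 6400.0):
            spec = StimulusSpec(zero_ipd, 1.0, 0.0, TWO_PI * bw, tone_present=True, snr=0.1)
            vals.append(effective_snr(spec, default_filter))
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=1e-6)

    def test_quadrature_oracle_900hz(self, default_filter):
        from scipy.integrate import quad
        from cohear import gammatone_power

        spec = StimulusSpec(zero_ipd, 1.0, 0.0, TWO_PI * 900.0, tone_present=True, snr=0.2)
        lo, hi = spec.band
        noise, _ = quad(
            lambda w: gammatone_power(default_filter, w) / spec.noise_bandwidth,
            lo, hi, limit=400,
        )
        assert effective_snr(spec, default_filter) == pytest.approx(0.2 / noise, rel=1e-8)

    def test_requires_tone(self, default_filter):
        with pytest.raises(ValueError, match="tone"):
            effective_snr(broadband_noise(), default_filter)


class TestMonauralSensitivity:
    def test_zero_snr(self, default_filter):
        spec = broadband_noise().with_tone(0.0)
        assert d_mon(spec, default_filter, ModelParams(0.9, 0.3, 0.76)) == 0.0

    def test_narrowband_definitional(self, default_filter):
        sigma_mon = 0.76
        spec = StimulusSpec(zero_ipd, 1.0, 0.0, TWO_PI * 0.79, tone_present=True, snr=sigma_mon)
        got = d_mon(spec, default_filter, ModelParams(0.9, 0.3, sigma_mon))
        assert got == pytest.approx(1.0, rel=0.01)

    def test_missing_monaural_path(self, default_filter):
        with pytest.raises(ValueError, match="monaural"):
            d_mon(broadband_noise().with_tone(0.1), default_filter, ModelParams(0.9, 0.3))


class TestCombinedSensitivity:
    def test_three_four_five(self):
        assert SensitivityBreakdown(3.0, 4.0).d_total == pytest.approx(5.0)

    def test_inphase_tone_in_coherent_noise_is_monaural_only(self, default_filter):
        # tone IPD equals the noise mean IPD: the binaural branch is silent
        params = ModelParams(0.9, 0.3, 0.76)
        noise = broadband_noise(tone_ipd=0.0)
        sb = d_total(noise, noise.with_tone(0.2), default_filter, params)
        assert sb.d_bin == pytest.approx(0.0, abs=1e-9)
        assert sb.d_total == pytest.approx(sb.d_mon)

    def test_n0spi_equals_npis0(self, default_filter):
        # anti-phasic tone in diotic noise vs diotic tone in anti-phasic
        # noise: the model predicts identical sensitivity
        params = ModelParams(0.97, 0.38, 0.76)
        snr = 0.05
        n0 = StimulusSpec(zero_ipd, 1.0, math.pi, TWO_PI * 900.0)
        npi = StimulusSpec(lambda w: np.full_like(np.asarray(w, float), math.pi),
                           1.0, 0.0, TWO_PI * 900.0)
        d1 = d_total(n0, n0.with_tone(snr), default_filter, params)
        d2 = d_total(npi, npi.with_tone(snr), default_filter, params)
        assert d1.d_total == pytest.approx(d2.d_total, rel=1e-9)

    def test_rejects_mismatched_noise(self, default_filter):
        params = ModelParams(0.9, 0.3, 0.76)
        with pytest.raises(ValueError, match="differ only by the added tone"):
            d_total(
                broadband_noise(rho=1.0),
                broadband_noise(rho=0.5).with_tone(0.1),
                default_filter,
                params,
            )


class TestThresholdSolver:
    def test_cue_free_threshold_matches_closed_form(self, default_filter):
        # no binaural cue: d' = SNR*h0/(I_auto*sigma_mon), invertible by hand
        params = ModelParams(0.97, 0.38, 0.76)
        spec = make_experiment_spec(
            "vandepar1999", {"noise_ipd_rad": 0.0, "tone_ipd_rad": 0.0, "bandwidth_hz": 5.0}
        )
        kernel = ThresholdKernel(spec, 0.0, default_filter)
        got = kernel.threshold_snr(params)
        closed = params.d_target * params.sigma_mon * kernel.i_auto / kernel.h0
        assert got == pytest.approx(closed, rel=1e-9)
        # narrowband: threshold ~ sigma_mon itself
        assert got == pytest.approx(params.sigma_mon, rel=0.01)

    def test_binaural_advantage_exists(self, default_filter):
        params = ModelParams(0.97, 0.38, 0.76)
        noise = broadband_noise()
        t_pi = solve_threshold_snr(noise, math.pi, default_filter, params)
        t_0 = solve_threshold_snr(noise, 0.0, default_filter, params)
        assert t_pi < t_0

    def test_3db_per_octave_at_large_bandwidth(self, default_filter):
        params = ModelParams(0.96, 0.40, 0.74)
        thr = {}
        for bw in (3200.0, 6400.0):
            noise = broadband_noise(bandwidth_hz=bw)
            thr[bw] = solve_threshold_snr(noise, math.pi, default_filter, params)
        diff_db = 10 * math.log10(thr[3200.0] / thr[6400.0])
        assert diff_db == pytest.approx(10 * math.log10(2.0), abs=0.02)

    def test_threshold_tolerance(self, default_filter):
        params = ModelParams(0.90, 0.19, 0.61)
        noise = broadband_noise(delta_t_ms=1.3)
        kernel = ThresholdKernel(noise, math.pi, default_filter)
        snr = kernel.threshold_snr(params)
        assert kernel.sensitivity(snr, params).d_total == pytest.approx(1.0, rel=1e-6)

    def test_no_cue_raises_with_bracket_diagnostic(self, default_filter):
        # in-phase tone in coherent noise with no monaural path: no solution
        params = ModelParams(0.9, 0.3, sigma_mon=None)
        with pytest.raises(ValueError, match="bracket"):
            solve_threshold_snr(broadband_noise(), 0.0, default_filter, params)

    @pytest.mark.parametrize(
        "study, cond",
        [
            ("robinson1963", {"rho_n": 0.5, "tone_ipd_rad": math.pi}),
            ("vanderheijden1999", {"delta_t_ms": 1.0, "tone_ipd_rad": math.pi}),
            ("rabiner1966", {"delta_t_ms": 2.0}),
            ("vandepar1999", {"noise_ipd_rad": 0.0, "tone_ipd_rad": 0.0, "bandwidth_hz": 100.0}),
        ],
    )
    def test_sensitivity_monotone_in_snr(self, study, cond, default_filter):
        # guards the root-finding bracket
        params = ModelParams(0.92, 0.31, 0.76)
        spec = make_experiment_spec(study, cond)
        kernel = ThresholdKernel(spec, spec.tone_ipd, default_filter)
        d = [kernel.sensitivity(s, params).d_total for s in np.logspace(-6, 4, 41)]
        assert np.all(np.diff(d) >= -1e-9)

    def test_level_invariance_of_threshold(self, default_filter):
        params = ModelParams(0.90, 0.19, 0.61)
        dens = build_cspd(broadband_noise(delta_t_ms=0.7))
        k1 = ThresholdKernel.from_densities(dens, math.pi, default_filter)
        k2 = ThresholdKernel.from_densities(dens.scaled(13.0), math.pi, default_filter)
        assert k2.threshold_snr(params) == pytest.approx(k1.threshold_snr(params), rel=1e-6)


class TestIncoherenceThreshold:
    def test_vanishing_criterion(self):
        params = ModelParams(0.92, 0.42, d_target=1e-9)
        assert incoherence_threshold(1.0, params) == pytest.approx(0.0, abs=1e-6)

    def test_against_bisection_oracle(self):
        params = ModelParams(0.92, 0.42)
        got = incoherence_threshold(1.0, params)

        def resid(drho):
            return (arctanh_ref(0.92) - arctanh_ref(0.92 * (1 - drho))) - 0.42

        lo, hi = 0.0, 2.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if resid(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert got == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    def test_sensitivity_highest_near_full_correlation(self):
        params = ModelParams(0.92, 0.42)
        assert incoherence_threshold(1.0, params) < incoherence_threshold(0.5, params)

    def test_unreachable_criterion(self):
        with pytest.raises(ValueError, match="unreachable"):
            incoherence_threshold(-0.9, ModelParams(0.92, 0.42, d_target=10.0))

    def test_rho_ref_domain(self):
        with pytest.raises(ValueError, match="rho_ref"):
            incoherence_threshold(1.5, ModelParams(0.9, 0.3))


class TestIpdDiscrimination:
    def test_vanishing_criterion(self):
        params = ModelParams(0.9, 0.19, d_target=1e-12)
        assert ipd_discrimination_threshold(params) == pytest.approx(0.0, abs=1e-9)

    def test_itd_equivalent_range_endpoints(self):
        # most sensitive and least sensitive published parameter sets
        low = ipd_threshold_as_itd(ModelParams(0.90, 0.19), 500.0) * 1e6
        high = ipd_threshold_as_itd(ModelParams(0.89, 0.52), 500.0) * 1e6
        assert round(low) == 41
        assert round(high) == 117

    def test_insufficient_resolution_errors(self):
        with pytest.raises(ValueError, match="arcsin"):
            ipd_discrimination_threshold(ModelParams(0.6, 5.0))
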
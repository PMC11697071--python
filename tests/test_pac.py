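"""Modulation indices vs brute-force oracles, surrogates, comodulograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somnopac as sp
from somnopac.core import ValidationError
from somnopac.pac import Comodulogram, PhaseAmplitudeSeries, comodulogram_peak

from conftest import make_tone

RATE = 400.0

# frozen N=8 fixture for the oracle-equivalence checks
FIX_AMP = np.array([0.7, 1.3, 2.1, 0.4, 1.8, 0.9, 1.1, 2.5])
FIX_PHASE = np.array([-2.9, -1.7, -0.4, 0.1, 0.8, 1.5, 2.2, 3.0])


def brute_force_mi(amp, phase):
    """Direct complex summation, one term at a time (the oracle)."""
    z = 0.0 + 0.0j
    for a, p in zip(amp, phase):
        z += a * complex(np.cos(p), np.sin(p))
    z /= len(amp)
    power = sum(a * a for a in amp) / len(amp)
    mi = abs(z)
    mi_norm = mi / (np.sqrt(len(amp)) * np.sqrt(power))
    return mi, mi_norm, np.angle(z)


def series(amp, phase):
    return PhaseAmplitudeSeries(phase=phase, amplitude=amp, sampling_rate_hz=RATE)


class TestModulationIndex:
    def test_matches_bruteforce_complex_sum(self):
        mi_o, min_o, ang_o = brute_force_mi(FIX_AMP, FIX_PHASE)
        res = sp.mi_canolty(series(FIX_AMP, FIX_PHASE))
        assert res.mi_canolty == pytest.approx(mi_o, rel=1e-12)
        assert res.mi_normalized == pytest.approx(min_o, rel=1e-12)
        assert res.mean_vector_angle == pytest.approx(ang_o, rel=1e-12)
        res2 = sp.mi_normalized(series(FIX_AMP, FIX_PHASE))
        assert res2.mi_normalized == pytest.approx(min_o, rel=1e-12)

    def test_constant_envelope_constant_phase_limits(self):
        c, phi0, n = 2.5, 0.7, 16
        s = series(np.full(n, c), np.full(n, phi0))
        res = sp.mi_canolty(s)
        assert res.mi_canolty == pytest.approx(c, rel=1e-14)
        assert res.mean_vector_angle == pytest.approx(phi0, rel=1e-14)
        assert res.mi_normalized == pytest.approx(1 / np.sqrt(n), rel=1e-14)

    def test_equally_spaced_phases_cancel(self):
        n = 16
        phases = -np.pi + 2 * np.pi * (np.arange(n) + 1) / n  # one full cycle
        res = sp.mi_canolty(series(np.full(n, 3.0), phases))
        assert res.mi_canolty < 1e-12

    def test_all_zero_envelope_rejects_normalized(self):
        s = series(np.zeros(8), FIX_PHASE)
        assert sp.mi_canolty(s).mi_canolty == 0.0
        with pytest.raises(ValidationError):
            sp.mi_normalized(s)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        k=st.floats(1e-3, 1e3),
        n=st.integers(2, 64),
    )
    def test_envelope_scaling_homogeneity(self, seed, k, n):
        rng = np.random.default_rng(seed)
        amp = rng.uniform(0.1, 5.0, n)
        phase = rng.uniform(-np.pi, np.pi, n)
        base = sp.mi_canolty(series(amp, phase))
        scaled = sp.mi_canolty(series(k * amp, phase))
        assert scaled.mi_canolty == pytest.approx(k * base.mi_canolty, rel=1e-9)
        assert scaled.mi_normalized == pytest.approx(base.mi_normalized, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 64))
    def test_mi_bounds(self, seed, n):
        rng = np.random.default_rng(seed)
        amp = rng.uniform(0.0, 5.0, n)
        phase = rng.uniform(-np.pi, np.pi, n)
        res = sp.mi_canolty(series(amp, phase))
        assert 0.0 <= res.mi_canolty <= np.mean(amp) + 1e-12
        if res.mi_normalized is not None:
            assert res.mi_normalized <= 1 / np.sqrt(n) + 1e-12


class TestExtraction:
    def test_tone_phase_slope(self):
        x = make_tone(8.0, 30)
        phase = sp.extract_phase(x, RATE, (7, 9))
        k = int(2 * RATE)
        unwrapped = np.unwrap(phase[k:-k])
        slope = np.polyfit(np.arange(unwrapped.size) / RATE, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 8, rel=1e-3)
        assert phase.min() > -np.pi - 1e-12 and phase.max() <= np.pi + 1e-12

    def test_time_reversal_negates_phase(self):
        x = make_tone(8.0, 20)
        fwd = sp.extract_phase(x, RATE, (7, 9))
        rev = sp.extract_phase(x[::-1], RATE, (7, 9))
        k = int(2 * RATE)
        lhs = np.exp(1j * rev[k:-k])
        rhs = np.conj(np.exp(1j * fwd[::-1][k:-k]))
        assert np.abs(np.angle(lhs * np.conj(rhs))).max() < 0.01

    def test_envelope_of_tone_is_amplitude(self):
        A = 2.0
        x = make_tone(100.0, 30, amplitude=A)
        env = sp.extract_amplitude(x, RATE, (90, 110))
        k = int(2 * RATE)
        assert np.allclose(env[k:-k], A, rtol=0.02)
        assert np.allclose(
            sp.extract_amplitude(-x, RATE, (90, 110)), env, rtol=1e-9, atol=1e-9
        )

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(sp.extract_amplitude(np.zeros(4000), RATE, (90, 110)), 0.0)


class TestPhaseHistogram:
    def test_full_coupling_peaks_at_zero_phase_bin(self, coupled_signal):
        bare = sp.StateProfile("REM", (), 0.0, 1.0, 0.0)
        x = sp.synthesize_state_segment(
            bare, sp.PacInjectionSpec(coupling_strength=1.0), 60.0, RATE, seed=3
        )
        s = sp.phase_amplitude_series(x, RATE, (7, 9), (90, 110))
        hist = sp.phase_sorted_amplitude_histogram(s, n_bins=18)
        peak_bin = int(np.argmax(hist.mean_amplitude))
        assert abs(hist.bin_centers[peak_bin]) < 2 * np.pi / 18

    def test_constant_envelope_uniform_bins(self):
        rng = np.random.default_rng(0)
        s = PhaseAmplitudeSeries(
            phase=rng.uniform(-np.pi, np.pi, 100_000),
            amplitude=np.full(100_000, 2.0),
            sampling_rate_hz=RATE,
        )
        hist = sp.phase_sorted_amplitude_histogram(s)
        assert np.allclose(hist.mean_amplitude, 2.0)

    def test_count_weighted_means_conserve_overall_mean(self):
        rng = np.random.default_rng(1)
        s = PhaseAmplitudeSeries(
            phase=rng.uniform(-np.pi, np.pi, 5000),
            amplitude=rng.uniform(0, 3, 5000),
            sampling_rate_hz=RATE,
        )
        hist = sp.phase_sorted_amplitude_histogram(s)
        pooled = np.sum(hist.mean_amplitude * hist.counts) / hist.counts.sum()
        assert pooled == pytest.approx(np.mean(s.amplitude), rel=1e-12)


class TestSurrogates:
    def test_strong_coupling_beats_all_surrogates(self, coupled_signal):
        s = sp.phase_amplitude_series(coupled_signal, RATE, (7, 9), (90, 110))
        null = sp.surrogate_test(s, n_surrogates=200, seed=4)
        assert null.p == pytest.approx(1 / 201)

    def test_p_range_and_determinism(self, coupled_signal):
        s = sp.phase_amplitude_series(coupled_signal, RATE, (7, 9), (90, 110))
        for scheme in ("circular_shift", "block_shuffle", "full_shuffle"):
            null = sp.surrogate_test(s, n_surrogates=30, scheme=scheme, seed=9)
            assert 1 / 31 <= null.p <= 1.0
            again = sp.surrogate_test(s, n_surrogates=30, scheme=scheme, seed=9)
            assert np.array_equal(null.null_mi, again.null_mi)

    def test_too_few_surrogates_rejected(self, coupled_signal):
        s = sp.phase_amplitude_series(coupled_signal, RATE, (7, 9), (90, 110))
        with pytest.raises(ValidationError):
            sp.surrogate_test(s, n_surrogates=10)


class TestComodulogram:
    def test_shape_matches_grids(self, coupled_signal):
        com = sp.comodulogram(
            coupled_signal, RATE,
            phase_freqs_hz=np.array([6.0, 8.0]),
            amp_freqs_hz=np.array([90.0, 100.0, 110.0]),
        )
        assert com.mi.shape == (2, 3)

    def test_peak_recovers_injected_coupling(self, coupled_signal):
        com = sp.comodulogram(
            coupled_signal, RATE,
            phase_freqs_hz=np.arange(6.0, 11.0),
            amp_freqs_hz=np.arange(90.0, 111.0),
        )
        fp, fa = comodulogram_peak(com)
        assert abs(fp - 8.0) <= 1.0
        assert abs(fa - 100.0) <= 1.0

    def test_tie_rule_picks_lowest_phase_then_amplitude(self):
        com = Comodulogram(
            phase_freqs_hz=np.array([3.0, 4.0]),
            amp_freqs_hz=np.array([50.0, 60.0]),
            mi=np.ones((2, 2)),
            method="canolty",
        )
        assert comodulogram_peak(com) == (3.0, 50.0)

    def test_no_coupling_yields_empty_holm_mask(self, rem_profile):
        empties = 0
        n_seeds = 8
        for r in range(n_seeds):
            x = sp.synthesize_state_segment(
                rem_profile,
                sp.PacInjectionSpec(coupling_strength=0.0),
                20.0, RATE, seed=500 + r,
            )
            com = sp.comodulogram(
                x, RATE,
                phase_freqs_hz=np.array([4.0, 8.0]),
                amp_freqs_hz=np.array([80.0, 100.0]),
                n_surrogates=99, seed=r,
            )
            empties += not com.significant.any()
        assert empties >= n_seeds - 1

    def test_grid_beyond_nyquist_rejected(self, coupled_signal):
        with pytest.raises(ValidationError):
            sp.comodulogram(
                coupled_signal, RATE, amp_freqs_hz=np.array([150.0, 199.0])
            )
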
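"""Generator contracts: Markov hypnograms, component RMS, coupling law, seeds."""

import numpy as np
import pytest

import somnopac as sp
from somnopac.core import ValidationError
from somnopac.synthetic import (
    _pink_noise,
    default_cohort_spec,
    default_profiles,
)

RATE = 400.0


class TestSimulateHypnogram:
    def test_absorbing_identity_matrix_stays_in_initial_state(self):
        hyp = sp.simulate_hypnogram(np.eye(3), 100, seed=0, initial_state="WAKE")
        assert len(hyp) == 100
        assert set(hyp.states) == {"WAKE"}

    def test_mean_bout_length_matches_geometric_expectation(self):
        # P(stay) = 0.9 for every state: geometric bouts with mean 1/(1-0.9)
        m = np.full((3, 3), 0.05) + np.eye(3) * 0.85
        hyp = sp.simulate_hypnogram(m, 100_000, seed=3)
        bouts = sp.extract_bouts(hyp)
        mean_len = np.mean([b.n_epochs for b in bouts])
        assert mean_len == pytest.approx(10.0, rel=0.05)

    def test_same_seed_reproduces_sequence(self):
        m = sp.synthetic.default_transition_matrix()
        a = sp.simulate_hypnogram(m, 500, seed=42)
        b = sp.simulate_hypnogram(m, 500, seed=42)
        assert np.array_equal(a.states, b.states)
        c = sp.simulate_hypnogram(m, 500, seed=43)
        assert not np.array_equal(a.states, c.states)

    def test_occupancy_converges_to_stationary_distribution(self):
        # well-mixing chain: 100k epochs give enough effective samples
        m = np.array([[0.80, 0.15, 0.05], [0.10, 0.85, 0.05], [0.30, 0.10, 0.60]])
        # stationary distribution oracle: left eigenvector of the matrix
        w, v = np.linalg.eig(m.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = pi / pi.sum()
        hyp = sp.simulate_hypnogram(m, 100_000, seed=7)
        occ = np.array(
            [np.mean(hyp.states == s) for s in sp.STATES]
        )
        assert np.abs(occ - pi).sum() < 0.02

    def test_rejects_non_stochastic_matrix(self):
        bad = np.full((3, 3), 0.5)
        with pytest.raises(ValidationError):
            sp.simulate_hypnogram(bad, 10, seed=0)


class TestStateSegment:
    def test_component_rms_matches_profile(self):
        prof = sp.StateProfile(
            "NREM", band_amplitudes=((2.0, 3.0, 40.0),), pink_noise_rms=0.0,
            pink_noise_exponent=1.0, emg_rms=0.0,
        )
        x = sp.synthesize_state_segment(prof, None, 60.0, RATE, seed=1)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(40.0, rel=0.10)

    def test_uncoupled_fast_component_has_flat_envelope(self, rem_profile):
        pac = sp.PacInjectionSpec(coupling_strength=0.0, carrier_rms=0.0)
        bare = sp.StateProfile("REM", (), 0.0, 1.0, 0.0)
        x = sp.synthesize_state_segment(bare, pac, 60.0, RATE, seed=2)
        env = sp.extract_amplitude(x, RATE, (90, 110))[800:-800]
        assert np.std(env) / np.mean(env) < 0.02

    def test_full_coupling_envelope_peaks_at_zero_phase(self):
        # modulation law: envelope maximal at the carrier's cosine peak
        bare = sp.StateProfile("REM", (), 0.0, 1.0, 0.0)
        pac = sp.PacInjectionSpec(coupling_strength=1.0)
        x = sp.synthesize_state_segment(bare, pac, 60.0, RATE, seed=5)
        series = sp.phase_amplitude_series(x, RATE, (7, 9), (90, 110))
        res = sp.mi_canolty(series)
        assert abs(res.mean_vector_angle) < 0.1

    def test_pink_noise_spectral_slope(self):
        x = _pink_noise(int(600 * RATE), RATE, 1.0, 1.0, np.random.default_rng(1))
        psd = sp.welch_psd(x, RATE, window_s=4.0)
        m = (psd.frequencies_hz >= 1) & (psd.frequencies_hz <= 100)
        slope = np.polyfit(
            np.log10(psd.frequencies_hz[m]), np.log10(psd.density[m]), 1
        )[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_rejects_component_beyond_nyquist(self):
        prof = sp.StateProfile("WAKE", ((250.0, 4.0, 5.0),), 0.0, 1.0, 0.0)
        with pytest.raises(ValidationError):
            sp.synthesize_state_segment(prof, None, 10.0, RATE, seed=0)


class TestRecording:
    def test_hypnogram_length_matches_duration(self):
        spec = default_cohort_spec(n_per_group=1, duration_h=24.0, seed=0)
        assert spec.n_epochs == 8640
        small = default_cohort_spec(n_per_group=1, duration_h=0.1, seed=0)
        rec, hyp = sp.synthesize_recording(small, "control", 0)
        assert len(hyp) == 36
        assert rec.n_samples == int(0.1 * 3600 * RATE)

    def test_all_nrem_recording_is_delta_dominant(self):
        spec = default_cohort_spec(n_per_group=1, duration_h=0.25, seed=0)
        spec.transition_matrix = np.array(
            [[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=float
        )
        spec.dark_transition_matrix = None
        rec, hyp = sp.synthesize_recording(spec, "control", 0)
        assert set(hyp.states[1:]) == {"NREM"}
        psd = sp.welch_psd(rec.channel("EEG1"), RATE)
        delta = sp.band_power(psd, sp.BandDefinition("delta", 0.5, 4))
        rest = psd.total_power() - delta
        assert delta > rest

    def test_subjects_get_distinct_streams(self):
        spec = default_cohort_spec(n_per_group=2, duration_h=0.05, seed=9)
        a, _ = sp.synthesize_recording(spec, "control", 0)
        b, _ = sp.synthesize_recording(spec, "control", 1)
        assert not np.allclose(a.data, b.data)
        a2, _ = sp.synthesize_recording(spec, "control", 0)
        assert np.array_equal(a.data, a2.data)

    def test_emg_rms_orders_states_per_epoch(self):
        spec = default_cohort_spec(n_per_group=1, duration_h=0.5, seed=4)
        rec, hyp = sp.synthesize_recording(spec, "control", 0)
        emg = rec.channel("EMG")
        n_per = int(10 * RATE)
        rms = np.array(
            [
                np.sqrt(np.mean(emg[i * n_per : (i + 1) * n_per] ** 2))
                for i in range(len(hyp))
            ]
        )
        by_state = {s: rms[hyp.states == s] for s in sp.STATES}
        for hi, lo in [("WAKE", "NREM"), ("NREM", "REM")]:
            a, b = by_state[hi], by_state[lo]
            if a.size == 0 or b.size == 0:
                continue
            # pairwise ordering frequency (Mann-Whitney U / mn)
            frac = np.mean(a[:, None] > b[None, :])
            assert frac >= 0.95
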
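"""Epoch features, rule-based scoring, bouts, and light/dark summaries."""

import numpy as np
import pytest

import somnopac as sp
from somnopac.architecture import (
    EpochFeatures,
    ScoringThresholds,
    compute_epoch_features,
    score_epochs,
    summarize_architecture,
)
from somnopac.synthetic import default_cohort_spec

from conftest import make_tone

RATE = 400.0


def recording_from_eeg(eeg, emg=None):
    emg = np.zeros_like(eeg) if emg is None else emg
    return sp.Recording(
        data=np.vstack([eeg, eeg, emg]),
        channel_labels=("EEG1", "EEG2", "EMG"),
        sampling_rate_hz=RATE,
    )


class TestEpochFeatures:
    def test_delta_tone_dominates_delta_fraction(self):
        rec = recording_from_eeg(make_tone(2.0, 30))
        feats = compute_epoch_features(rec)
        assert feats.n_epochs == 3
        assert np.all(feats.delta_fraction > 0.9)

    def test_zero_emg_gives_zero_rms(self):
        rec = recording_from_eeg(make_tone(2.0, 25))
        feats = compute_epoch_features(rec)
        assert np.all(feats.emg_rms_uv == 0)
        assert feats.n_epochs == 2  # floor(25 s / 10 s)


class TestScoreEpochs:
    def features(self, emg, delta_frac, theta_delta, eeg_rms=40.0, n=1):
        return EpochFeatures(
            eeg_rms_uv=np.full(n, eeg_rms),
            delta_fraction=np.full(n, delta_frac),
            theta_delta_ratio=np.full(n, theta_delta),
            emg_rms_uv=np.full(n, emg),
        )

    def test_high_emg_forces_wake_regardless_of_eeg(self):
        feats = self.features(emg=30.0, delta_frac=0.9, theta_delta=5.0)
        assert score_epochs(feats).states[0] == "WAKE"

    def test_delta_dominant_low_emg_is_nrem(self):
        feats = self.features(emg=5.0, delta_frac=0.8, theta_delta=0.2)
        assert score_epochs(feats).states[0] == "NREM"

    def test_theta_dominant_low_voltage_atonia_is_rem(self):
        feats = self.features(emg=2.0, delta_frac=0.2, theta_delta=8.0, eeg_rms=30.0)
        assert score_epochs(feats).states[0] == "REM"

    def test_featureless_noise_scores_single_state(self):
        feats = self.features(emg=5.0, delta_frac=0.3, theta_delta=1.0, n=50)
        hyp = score_epochs(feats)
        assert len(set(hyp.states)) == 1  # deterministic fallback, no flapping

    def test_scorer_recovers_generator_ground_truth(self):
        spec = default_cohort_spec(n_per_group=1, duration_h=0.5, seed=21)
        rec, truth = sp.synthesize_recording(spec, "control", 0)
        feats = compute_epoch_features(rec)
        acc = np.mean(score_epochs(feats).states == truth.states)
        assert acc >= 0.90

    def test_accuracy_increases_with_feature_separation(self):
        spec = default_cohort_spec(n_per_group=1, duration_h=0.25, seed=22)
        rec, truth = sp.synthesize_recording(spec, "control", 0)
        feats = compute_epoch_features(rec)
        good = np.mean(score_epochs(feats).states == truth.states)
        # collapse the EMG separation: wake cut above the wake EMG level
        blurred = ScoringThresholds(emg_wake_cut_uv=45.0)
        bad = np.mean(score_epochs(feats, blurred).states == truth.states)
        assert good >= bad


class TestBouts:
    def test_run_length_decomposition(self):
        hyp = sp.Hypnogram(np.array(["WAKE", "WAKE", "NREM", "NREM", "NREM", "REM"]))
        bouts = sp.extract_bouts(hyp)
        assert [(b.state, b.n_epochs) for b in bouts] == [
            ("WAKE", 2), ("NREM", 3), ("REM", 1)
        ]
        assert bouts[1].duration_s == 30.0
        assert sum(b.n_epochs for b in bouts) == len(hyp)

    def test_single_state_single_bout(self):
        hyp = sp.Hypnogram(np.array(["REM"] * 7))
        assert len(sp.extract_bouts(hyp)) == 1

    def test_markov_bout_durations_match_geometric_closed_form(self):
        m = np.array([[0.9, 0.08, 0.02], [0.05, 0.9, 0.05], [0.2, 0.0, 0.8]])
        hyp = sp.simulate_hypnogram(m, 100_000, seed=13)
        bouts = sp.extract_bouts(hyp)
        for i, s in enumerate(sp.STATES):
            durs = [b.duration_s for b in bouts if b.state == s]
            expected = 10.0 / (1 - m[i, i])
            assert np.mean(durs) == pytest.approx(expected, rel=0.05)


class TestSummarizeArchitecture:
    def test_alternating_pattern_counts(self):
        n = 4320  # 12 h of 10-s epochs
        labels = np.tile(["WAKE", "NREM"], n // 2)
        hyp = sp.Hypnogram(labels)
        summary = summarize_architecture(hyp, block_hours=12.0)
        block = summary.blocks[0]
        n_nrem = n // 2
        assert block.arousals["NREM->WAKE"] == n_nrem - 1  # last NREM has no successor
        assert block.mean_bout_duration_s["NREM"] == 10.0
        assert block.percent_time["WAKE"] == pytest.approx(50.0)

    def test_all_wake_block(self):
        hyp = sp.Hypnogram(np.array(["WAKE"] * 360))
        summary = summarize_architecture(hyp, block_hours=1.0)
        block = summary.blocks[0]
        assert block.percent_time["WAKE"] == 100.0
        assert block.arousals["NREM->WAKE"] == 0
        assert block.arousals["REM->WAKE"] == 0

    def test_percentages_sum_to_100_per_block(self):
        m = sp.synthetic.default_transition_matrix()
        hyp = sp.simulate_hypnogram(m, 8640, seed=2)
        summary = summarize_architecture(hyp, block_hours=12.0)
        assert len(summary.blocks) == 2
        labels = [b.block_label for b in summary.blocks]
        assert labels == ["light", "dark"]
        for b in summary.blocks:
            assert sum(b.percent_time.values()) == pytest.approx(100.0, abs=1e-9)
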
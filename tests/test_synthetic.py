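"""Generator properties: layout geometry, source waveforms, epoch statistics."""

import numpy as np
import pytest

from megfix.errors import InvalidConfigError, InvalidLayoutError
from megfix.synthetic import (
    SimulationConfig,
    make_ground_truth,
    make_layout,
    simulate_epochs,
    simulate_gaze_log,
    simulate_sources,
)


class TestLayout:
    def test_full_size_layout_counts(self):
        layout = make_layout(204, 0.1, seed=7)
        assert layout.n_channels == 204
        n_frontal = int(layout.frontal_mask.sum())
        assert 15 <= n_frontal <= 25  # ~10% of 204
        assert np.all(np.hypot(*layout.positions.T) <= 1.0)

    def test_minimum_layout_has_proper_frontal_subset(self):
        layout = make_layout(2, 0.5, seed=0)
        assert int(layout.frontal_mask.sum()) == 1

    @pytest.mark.parametrize("n", [3, 1, 0])
    def test_odd_or_too_small_channel_count_rejected(self, n):
        with pytest.raises(InvalidLayoutError):
            make_layout(n, 0.1, 0)

    def test_positions_unique_within_pairs(self):
        layout = make_layout(32, 0.2, seed=1)
        assert len({tuple(p) for p in np.round(layout.positions, 9)}) == 32

    def test_frontal_channels_sit_at_top_of_head_map(self):
        layout = make_layout(204, 0.1, seed=3)
        y = layout.positions[:, 1]
        assert y[layout.frontal_mask].min() > np.median(y)


class TestGroundTruth:
    def test_mixing_columns_unit_norm(self, small_dataset):
        norms = np.linalg.norm(small_dataset.truth.A_true, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_artifact_source_loads_frontally(self):
        cfg = SimulationConfig(n_channels=204, k_true=6, seed=2)
        layout = make_layout(204, 0.1, seed=2)
        truth = make_ground_truth(cfg, layout)
        a = np.abs(truth.A_true[:, truth.source_kinds.index("artifact")])
        frontal_share = a[layout.frontal_mask].sum() / a.sum()
        assert frontal_share > 0.5

    def test_slow_source_loads_off_frontal_band(self):
        cfg = SimulationConfig(n_channels=204, k_true=6, seed=2)
        layout = make_layout(204, 0.1, seed=2)
        truth = make_ground_truth(cfg, layout)
        a = np.abs(truth.A_true[:, truth.source_kinds.index("slow-deflection")])
        assert a[layout.frontal_mask].sum() / a.sum() < 0.2


class TestSources:
    def _setup(self, **kw):
        cfg = SimulationConfig(n_channels=32, k_true=5, seed=0, **kw)
        layout = make_layout(32, 0.2, seed=0)
        return cfg, make_ground_truth(cfg, layout)

    def test_null_amplitudes_make_classes_identically_distributed(self):
        cfg, truth = self._setup(slow_amplitude=0.0, evoked_amplitude=0.0)
        s0 = simulate_sources(cfg, truth, 0, np.random.default_rng(42))
        s1 = simulate_sources(cfg, truth, 1, np.random.default_rng(42))
        np.testing.assert_array_equal(s0, s1)

    def test_slow_ramp_reaches_amplitude_at_feedback_time(self):
        cfg, truth = self._setup(slow_amplitude=2.5)
        s = simulate_sources(cfg, truth, 1, np.random.default_rng(0))
        t = cfg.times()
        slow = s[truth.source_kinds.index("slow-deflection")]
        i_fb = int(np.argmin(np.abs(t - 0.5)))
        assert slow[i_fb] == pytest.approx(2.5, rel=1e-6)  # sin(pi/2) = 1
        assert np.all(slow[t < 0] == 0.0)
        # held constant after feedback
        np.testing.assert_allclose(slow[t > 0.5], 2.5, rtol=1e-6)

    def test_slow_source_absent_in_spontaneous_class(self):
        cfg, truth = self._setup()
        s = simulate_sources(cfg, truth, 0, np.random.default_rng(0))
        assert np.all(s[truth.source_kinds.index("slow-deflection")] == 0.0)

    def test_oscillatory_random_phase_zero_mean(self):
        cfg, truth = self._setup()
        rng = np.random.default_rng(123)
        osc_idx = truth.source_kinds.index("oscillatory")
        vals = np.array([simulate_sources(cfg, truth, 0, rng)[osc_idx, 350] for _ in range(1000)])
        # empirical mean of sin(phase + const) over uniform phases
        assert abs(vals.mean()) < 4 * vals.std() / np.sqrt(len(vals))

    def test_invalid_label_rejected(self):
        cfg, truth = self._setup()
        with pytest.raises(InvalidConfigError):
            simulate_sources(cfg, truth, 2, np.random.default_rng(0))


class TestEpochs:
    def test_zero_noise_zero_amplitudes_gives_zero_epochs(self):
        cfg = SimulationConfig(
            n_voluntary=4, n_spontaneous=4, n_channels=8, k_true=4,
            slow_amplitude=0, evoked_amplitude=0, artifact_amplitude=0,
            background_amplitude=0, noise_sd=0, seed=0,
        )
        ds = simulate_epochs(cfg)
        assert np.all(ds.epochs == 0)

    def test_pure_noise_variance_matches_noise_sd(self):
        cfg = SimulationConfig(
            n_voluntary=100, n_spontaneous=100, n_channels=16, k_true=4,
            epoch_window=(-0.1, 0.4), slow_amplitude=0, evoked_amplitude=0,
            artifact_amplitude=0, background_amplitude=0, noise_sd=1.0, seed=9,
        )
        ds = simulate_epochs(cfg)
        var = ds.epochs.var()
        n = ds.epochs.size
        se = np.sqrt(2.0 / n)  # SE of a pooled variance estimate of N(0,1) data
        assert abs(var - 1.0) < 3 * se

    def test_same_seed_bit_identical(self, small_config):
        a = simulate_epochs(small_config)
        b = simulate_epochs(small_config)
        np.testing.assert_array_equal(a.epochs, b.epochs)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_label_counts_match_config(self, small_dataset, small_config):
        assert (small_dataset.labels == 1).sum() == small_config.n_voluntary
        assert (small_dataset.labels == 0).sum() == small_config.n_spontaneous

    def test_epochs_finite_and_correct_length(self, small_dataset, small_config):
        assert np.isfinite(small_dataset.epochs).all()
        assert small_dataset.epochs.shape[2] == small_config.n_times

    def test_nonpositive_trial_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_voluntary=0, n_spontaneous=10)

    def test_effect_monotone_in_slow_amplitude(self):
        """Grand-average class difference on slow-loaded channels grows with amplitude."""
        diffs = []
        for amp in (0.5, 1.0, 2.0):
            cfg = SimulationConfig(
                n_voluntary=200, n_spontaneous=200, n_channels=32, k_true=5,
                epoch_window=(-0.1, 0.5), slow_amplitude=amp, seed=21,
            )
            ds = simulate_epochs(cfg)
            slow_col = ds.truth.A_true[:, ds.truth.source_kinds.index("slow-deflection")]
            chans = np.argsort(np.abs(slow_col))[-5:]
            t = cfg.times()
            late = t > 0.25
            d = (
                ds.epochs[ds.labels == 1][:, chans][:, :, late].mean()
                - ds.epochs[ds.labels == 0][:, chans][:, :, late].mean()
            )
            diffs.append(np.sign(slow_col[chans].mean()) * d)
        assert diffs[0] < diffs[1] < diffs[2]


class TestGazeLog:
    def test_no_spontaneous_all_dwells_confirmed_timely(self):
        df = simulate_gaze_log(40, p_spontaneous=0.0, seed=1)
        balls = df[df.kind == "ball_dwell"].reset_index(drop=True)
        assert (balls.truth_intent == "voluntary").all()
        for _, row in balls.iterrows():
            nxt = df[df.onset_ms > row.onset_ms].iloc[0]
            assert nxt.kind == "confirm_fix"
            assert nxt.onset_ms - row.offset_ms <= 200

    def test_all_spontaneous_emits_no_confirmations(self):
        df = simulate_gaze_log(40, p_spontaneous=1.0, seed=2)
        assert not (df.kind == "confirm_fix").any()

    def test_events_ordered_and_non_overlapping(self):
        df = simulate_gaze_log(60, 0.5, seed=3, boundary_fraction=0.2)
        assert (df.onset_ms.diff().dropna() > 0).all()
        assert (df.onset_ms.values[1:] >= df.offset_ms.values[:-1]).all()

    def test_boundary_cases_present_in_fixed_rotation(self):
        df = simulate_gaze_log(200, 0.5, seed=4, boundary_fraction=0.3)
        kinds = set(df.truth_intent)
        assert {"excluded-delayed-confirmation", "excluded-late-onset", "excluded-below-threshold"} <= kinds

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_gaze_log(10, 1.5, 0)
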
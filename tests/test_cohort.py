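"""Synthetic cohort generator: oscillator model, observables, motion,
events, behaviour, and the on-disk round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metanet as mn
from metanet.cohort import (
    _simulate_phases_multi,
    generate_behavior,
    gordon_like_network_sizes,
)
from metanet.preprocess import framewise_displacement, select_task_frames


def _config(**kw) -> mn.SimulationConfig:
    defaults = dict(
        n_subjects=1,
        n_frames=200,
        coupling={"rest": (4.0, 0.8)},
        coupling_jitter_sd=0.0,
        seed=7,
    )
    defaults.update(kw)
    return mn.SimulationConfig(**defaults)


class TestSimulatePhases:
    def test_uncoupled_identical_oscillators_keep_phase_differences(self):
        """With no coupling, no noise and equal frequencies, pairwise
        phase differences are frozen at their initial values."""
        cfg = _config(coupling={"rest": (0.0, 0.0)}, phase_noise_sd=0.0)
        pa = mn.simulate_phases(cfg, "rest", freqs=0.09)
        diffs = np.angle(np.exp(1j * (pa.data - pa.data[:, :1])))
        drift = np.abs(diffs - diffs[0]).max()
        assert drift < 1e-9

    def test_identical_initial_phases_stay_fully_locked(self):
        cfg = _config(coupling={"rest": (0.0, 0.0)}, phase_noise_sd=0.0)
        pa = mn.simulate_phases(cfg, "rest", freqs=0.09, init_phases=0.3)
        R = mn.order_parameter(pa)
        assert np.allclose(R, 1.0, atol=1e-12)

    def test_coupling_raises_time_mean_order_parameter(self):
        """Same seed, stronger within-network coupling -> higher mean R
        (the simulation itself is the oracle at the two settings)."""
        means = []
        for kw in (0.0, 5.0):
            cfg = _config(coupling={"rest": (kw, 0.0)}, seed=3, n_frames=400)
            pa = mn.simulate_phases(cfg, "rest")
            cols = [i for i, r in enumerate(cfg.region_ids) if r.startswith("visual")]
            means.append(mn.order_parameter(pa.data[:, cols]).mean())
        assert means[1] > means[0]

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError, match="unknown condition"):
            mn.simulate_phases(_config(), "no-such-task")

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            mn.SimulationConfig(coupling={"rest": (np.nan, 0.0)})

    def test_output_wrapped_and_reproducible(self):
        cfg = _config(seed=9)
        a = mn.simulate_phases(cfg, "rest").data
        b = mn.simulate_phases(cfg, "rest").data
        assert np.array_equal(a, b)
        assert a.min() >= -np.pi and a.max() < np.pi


@pytest.fixture(scope="module")
def coupling_scan():
    out = {}
    for kw in (0.0, 1.0, 5.0, 20.0, 50.0):
        cfg = _config(coupling={"rest": (kw, 0.0)}, seed=3, n_frames=600)
        pa = mn.simulate_phases(cfg, "rest")
        cols = [i for i, r in enumerate(cfg.region_ids)
                if r.startswith("default_mode")]
        R = mn.order_parameter(pa.data[:, cols])
        out[kw] = (R.mean(), R.std())
    return out


class TestDynamicsProperties:
    def test_synchrony_monotone_in_coupling(self, coupling_scan):
        means = [coupling_scan[k][0] for k in (0.0, 1.0, 5.0, 20.0)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_metastability_peaks_at_intermediate_coupling(self, coupling_scan):
        """Criticality signature: fluctuations of R are largest between
        the incoherent and fully locked regimes."""
        assert coupling_scan[5.0][1] > coupling_scan[0.0][1]
        assert coupling_scan[5.0][1] > coupling_scan[50.0][1]


class TestRenderBold:
    def test_pure_sinusoid_readout(self):
        cfg = _config(obs_noise_sd=0.0)
        pa = mn.simulate_phases(cfg, "rest")
        ts = mn.render_bold(pa, cfg)
        assert np.array_equal(ts.data, np.sin(pa.data))
        assert np.abs(ts.data).max() <= 1.0

    def test_variance_of_noisy_tone_matches_analytic_value(self):
        """A uniformly drifting phase read out through sin plus white
        noise has variance 0.5 + sigma^2."""
        cfg = _config(n_frames=10_000, obs_noise_sd=0.3)
        theta = (2 * np.pi * 0.09 * np.arange(10_000) * cfg.tr_s) % (2 * np.pi)
        pa = mn.PhaseArray(theta[:, None] - np.pi, tr_s=cfg.tr_s)
        ts = mn.render_bold(pa, cfg, rng=np.random.default_rng(0))
        expected = 0.5 + 0.3**2
        assert abs(ts.data.var() / expected - 1) < 0.05

    def test_confound_mixture_added_uniformly(self):
        cfg = _config(n_confounds=2)
        pa = mn.simulate_phases(cfg, "rest")
        conf = mn.simulate_confounds(cfg, 0, "rest")
        ts = mn.render_bold(pa, cfg, confounds=conf, confound_weights=[0.5, -0.2])
        mix = conf @ np.array([0.5, -0.2])
        assert np.allclose(ts.data - np.sin(pa.data), mix[:, None])

    def test_confound_shape_mismatch_raises(self):
        cfg = _config()
        pa = mn.simulate_phases(cfg, "rest")
        with pytest.raises(ValueError, match="frames"):
            mn.render_bold(pa, cfg, confounds=np.zeros((5, 2)))


class TestSimulateMotion:
    def test_no_steps_no_spikes_gives_zero_fd(self):
        cfg = _config(motion_step_sd=0.0, motion_spike_rate=0.0)
        fd = framewise_displacement(mn.simulate_motion(cfg, 0, "rest"))
        assert np.all(fd == 0)

    def test_single_spike_appears_in_fd_once(self):
        cfg = _config(motion_step_sd=0.0, motion_spike_rate=0.0)
        motion = mn.simulate_motion(cfg, 0, "rest")
        motion[50:, 1] += 1.0  # persistent 1 mm step on one axis
        fd = framewise_displacement(motion)
        assert fd[50] == pytest.approx(1.0)
        assert np.sum(fd > 0) == 1

    def test_spike_rate_matches_binomial_oracle(self):
        p, frames = 0.02, 5000
        cfg = _config(n_frames=frames, motion_step_sd=0.0,
                      motion_spike_rate=p, spike_mm=1.0, seed=0)
        fd = framewise_displacement(mn.simulate_motion(cfg, 0, "rest"))
        frac = np.mean(fd > 0.5)
        half = 2.576 * np.sqrt(p * (1 - p) / frames)  # 99% binomial interval
        assert p - half <= frac <= p + half


class TestEvents:
    def test_zero_cue_and_fixation_yields_single_spanning_block(self):
        cfg = _config(n_frames=100)
        scheme = mn.BlockScheme(cue_s=0.0, fixation_s=0.0,
                                task_s=100 * cfg.tr_s, n_blocks=1)
        ev = mn.generate_events(cfg, scheme)
        assert len(ev) == 1
        assert ev.iloc[0]["trial_type"] == "task"
        assert ev.iloc[0]["duration"] == pytest.approx(100 * cfg.tr_s)

    def test_retained_frames_match_block_bookkeeping(self):
        cfg = _config(n_frames=400)
        ev = mn.generate_events(cfg)
        pa = mn.simulate_phases(cfg, "rest")
        sel, _ = select_task_frames(pa, ev)
        expected = sum(
            int(np.floor(row["duration"] / cfg.tr_s))
            for _, row in ev.iterrows() if row["trial_type"] == "task"
        )
        # midpoint rule retains floor or ceil depending on alignment
        assert abs(sel.n_frames - expected) <= ev["trial_type"].eq("task").sum()

    def test_randomized_order_reproducible_under_seed(self):
        cfg = _config(n_frames=600)
        scheme = mn.BlockScheme(task_durations_s=[10.0, 20.0, 30.0, 15.0],
                                randomize=True)
        a = mn.generate_events(cfg, scheme)
        b = mn.generate_events(cfg, scheme)
        pd.testing.assert_frame_equal(a, b)


class TestBehavior:
    def test_zero_slope_gives_no_correlation(self, cohort):
        model = mn.BehaviorModel(slope=0.0, noise_sd=1.0)
        cfg = mn.SimulationConfig(
            n_subjects=50, n_frames=120, coupling={"rest": (4.0, 0.8)}, seed=5
        )
        c = mn.simulate_cohort(cfg)
        tab = generate_behavior(c, model)
        r = np.corrcoef(tab["score"], tab["metastability_target"])[0, 1]
        assert abs(r) < 2 / np.sqrt(50)

    def test_noiseless_scores_perfectly_correlated(self, cohort):
        model = mn.BehaviorModel(slope=0.5, noise_sd=0.0)
        tab = generate_behavior(cohort, model)
        r = np.corrcoef(tab["score"], tab["metastability_target"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_unknown_target_connection_raises(self, cohort):
        with pytest.raises(KeyError):
            generate_behavior(cohort, mn.BehaviorModel(connection=("a", "b")))

    def test_slope_recovery_covered_by_ols_confidence_interval(self):
        """With scores regenerated over noise draws, the OLS 95% CI
        covers the planted slope at close to the nominal rate."""
        cfg = mn.SimulationConfig(
            n_subjects=100, n_frames=120, coupling={"rest": (4.0, 0.8)}, seed=21
        )
        c = mn.simulate_cohort(cfg)
        m = c.behavior["metastability_target"].to_numpy()
        rng = np.random.default_rng(99)
        b, sd = 0.5, 0.004
        X = np.column_stack([np.ones_like(m), m])
        covered = 0
        for _ in range(100):
            y = 1.0 + b * m + rng.normal(0, sd, size=m.size)
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            s2 = (resid**2).sum() / (len(y) - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            tcrit = stats.t.ppf(0.975, len(y) - 2)
            covered += beta[1] - tcrit * se <= b <= beta[1] + tcrit * se
        assert covered >= 90


class TestCohortBundle:
    def test_seed_determinism(self):
        cfg = dict(n_subjects=2, n_frames=80, coupling={"rest": (4.0, 0.8)}, seed=13)
        a = mn.simulate_cohort(mn.SimulationConfig(**cfg))
        b = mn.simulate_cohort(mn.SimulationConfig(**cfg))
        for key in a.data:
            assert np.array_equal(a.data[key].ts.data, b.data[key].ts.data)
            assert np.array_equal(a.data[key].motion, b.data[key].motion)
        pd.testing.assert_frame_equal(a.behavior, b.behavior)

    def test_true_interaction_matrices_symmetric_and_shaped(self, cohort):
        for M in cohort.true_metastability.values():
            assert M.values.shape == (14, 14)
            assert np.allclose(M.values, M.values.T)
            assert M.values.min() >= 0 and M.values.max() <= 0.5

    def test_frequencies_are_trait_like_across_conditions(self, small_config):
        from metanet.cohort import _subject_traits

        f1, _ = _subject_traits(small_config, 0)
        f2, _ = _subject_traits(small_config, 0)
        f3, _ = _subject_traits(small_config, 1)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, f3)

    def test_full_scale_geometry_available(self):
        sizes = gordon_like_network_sizes()
        assert sum(sizes.values()) == 334
        assert sizes["thalamus"] == 1
        assert len(sizes) == 14


class TestRoundTrip:
    def test_write_then_read_is_lossless(self, cohort, tmp_path):
        manifest = mn.write_cohort(cohort, tmp_path)
        signals, motion, confounds, events, assignment, behavior, echo = \
            mn.read_cohort(tmp_path)
        for key, d in cohort.data.items():
            assert np.abs(signals[key].data - d.ts.data).max() < 1e-12
            assert np.abs(motion[key] - d.motion).max() < 1e-12
        assert assignment.labels == cohort.assignment.labels
        assert echo["seed"] == cohort.config.seed

    def test_manifest_enumerates_expected_files(self, cohort, tmp_path):
        manifest = mn.write_cohort(cohort, tmp_path)
        n_sc = cohort.config.n_subjects * len(cohort.conditions)
        n_task_conditions = sum(1 for c in cohort.conditions if c != "rest")
        assert len(manifest["files"]) == 3 * n_sc + n_task_conditions + 4
        for f in manifest["files"]:
            assert (tmp_path / f).exists()
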
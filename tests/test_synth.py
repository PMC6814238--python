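"""Generator contracts: determinism, design counts, latent structure, dial."""

import numpy as np
import pandas as pd
import pytest

from aesthdyn import SimulationConfig, simulate_experiment
from aesthdyn.config import Dist
from aesthdyn.synth import (generate_latent_trace, simulate_dial_events)
from aesthdyn.variability import rmsd
from conftest import constant_population, make_profile, make_stimulus


class TestLatentTrace:
    def test_full_shared_weight_makes_participants_identical(self):
        cfg = SimulationConfig()
        stim = make_stimulus()
        a = make_profile(participant_id="A", w_shared=1.0, session_noise_sd=0,
                         mean_bias=0.3, affinity_dance=0.2)
        b = make_profile(participant_id="B", w_shared=1.0, session_noise_sd=0)
        ta = generate_latent_trace(a, stim, "test", cfg, seed=1)
        tb = generate_latent_trace(b, stim, "test", cfg, seed=1)
        assert np.array_equal(ta, tb)

    def test_zero_shared_weight_decorrelates_participants(self):
        """Monte-Carlo oracle: mean r over >=100 stimulus draws is near 0."""
        cfg = SimulationConfig()
        a = make_profile(participant_id="A", w_shared=0.0, session_noise_sd=0)
        b = make_profile(participant_id="B", w_shared=0.0, session_noise_sd=0)
        rs = []
        for j in range(120):
            stim = make_stimulus(stimulus_id=f"S{j:03d}")
            ta = generate_latent_trace(a, stim, "test", cfg, seed=2)
            tb = generate_latent_trace(b, stim, "test", cfg, seed=2)
            rs.append(np.corrcoef(ta, tb)[0, 1])
        assert abs(float(np.mean(rs))) < 0.1

    def test_no_session_noise_means_identical_retest(self):
        cfg = SimulationConfig()
        p = make_profile(session_noise_sd=0.0)
        stim = make_stimulus()
        t1 = generate_latent_trace(p, stim, "test", cfg, seed=3)
        t2 = generate_latent_trace(p, stim, "retest", cfg, seed=3)
        assert np.array_equal(t1, t2)

    def test_trace_is_bounded_and_right_length(self):
        cfg = SimulationConfig()
        p = make_profile(session_noise_sd=0.8, mean_bias=0.9)
        t = generate_latent_trace(p, make_stimulus(), "retest", cfg, seed=4)
        assert t.shape == (cfg.n_samples,)
        assert np.all(t >= -1) and np.all(t <= 1)

    def test_invalid_session_label_raises(self):
        with pytest.raises(ValueError, match="session"):
            generate_latent_trace(make_profile(), make_stimulus(),
                                  "third", SimulationConfig(), seed=0)

    def test_invalid_profile_parameters_raise(self):
        with pytest.raises(ValueError):
            make_profile(w_shared=1.5)
        with pytest.raises(ValueError):
            make_profile(tau_integration=0.0)
        with pytest.raises(ValueError):
            make_profile(session_noise_sd=-0.1)
        with pytest.raises(ValueError):
            make_profile(mean_bias=float("nan"))


class TestDialEvents:
    def test_huge_dead_zone_emits_no_events(self, rng):
        latent = rng.uniform(-1, 1, 300)
        log = simulate_dial_events(latent, make_profile(dead_zone=2.5), 10.0)
        assert len(log) == 0

    def test_neutral_latent_emits_no_events(self):
        log = simulate_dial_events(np.zeros(300), make_profile(), 10.0)
        assert len(log) == 0

    def test_empty_latent_raises(self):
        with pytest.raises(ValueError):
            simulate_dial_events(np.array([]), make_profile(), 10.0)

    def test_timestamps_strictly_increasing_within_clip(self, rng):
        latent = np.clip(rng.normal(0, 0.5, 300), -1, 1)
        log = simulate_dial_events(latent, make_profile(dead_zone=0.0), 10.0)
        assert len(log) > 0
        assert np.all(np.diff(log.t_sec) > 0)
        assert log.t_sec.min() >= 0 and log.t_sec.max() < 30.0

    def test_shorter_lag_gives_more_variable_trace(self):
        """At a fixed dead zone, a faster dial yields a larger rmsd."""
        cfg = SimulationConfig()
        stim = make_stimulus()
        latent = generate_latent_trace(make_profile(session_noise_sd=0),
                                       stim, "test", cfg, seed=5)
        from aesthdyn.timeseries import events_to_trace
        r = {}
        for name, tau in (("fast", 0.2), ("slow", 5.0)):
            p = make_profile(tau_integration=tau, dead_zone=0.03)
            log = simulate_dial_events(latent, p, 10.0)
            r[name] = rmsd(events_to_trace(log.t_sec, log.position, 30.0, 10.0))
        assert r["fast"] > r["slow"]

    def test_observed_rmsd_ordering_matches_responsiveness_parameter(self):
        """The derived responsiveness score predicts the rmsd ordering of two
        dial configurations, including the counter-intuitive case where a
        wide dead zone *raises* rmsd through rare large jumps."""
        from aesthdyn.synth import dial_responsiveness
        from aesthdyn.timeseries import events_to_trace
        cfg = SimulationConfig()
        stim = make_stimulus()
        latent = generate_latent_trace(make_profile(session_noise_sd=0),
                                       stim, "test", cfg, seed=5)
        configs = {"a": (0.2, 0.01), "b": (5.0, 0.2)}
        observed, derived = {}, {}
        for name, (tau, dz) in configs.items():
            p = make_profile(tau_integration=tau, dead_zone=dz)
            log = simulate_dial_events(latent, p, 10.0)
            observed[name] = rmsd(
                events_to_trace(log.t_sec, log.position, 30.0, 10.0))
            derived[name] = dial_responsiveness(tau, dz)
        assert ((observed["a"] > observed["b"])
                == (derived["a"] > derived["b"]))


class TestExperimentDesign:
    def test_design_counts_full_size(self, default_dataset):
        # 50 observers x 30 clips x 2 sessions overall ratings;
        # continuous trials: rate x both sessions + view x retest only
        assert len(default_dataset.overall) == 3000
        assert default_dataset.traces().shape == (2250, 300)

    def test_view_group_has_no_test_session_events(self, default_dataset):
        ev = default_dataset.events
        assert len(ev[(ev.group == "view") & (ev.session == "test")]) == 0

    def test_same_seed_gives_identical_dataset(self, small_config):
        a = simulate_experiment(small_config)
        b = simulate_experiment(small_config)
        assert a.equals(b)

    def test_different_seed_gives_different_dataset(self, small_config, small_dataset):
        import dataclasses
        other = dataclasses.replace(small_config, rng_seed=small_config.rng_seed + 1)
        assert not simulate_experiment(other).equals(small_dataset)

    def test_category_shift_orders_category_means(self, default_dataset):
        means = default_dataset.overall.groupby("category")["rating"].mean()
        assert means["landscape"] > means["dance"]

    def test_ground_truth_parameters_are_retained(self, small_dataset):
        cols = set(small_dataset.participants.columns)
        assert {"w_shared", "tau_integration", "dead_zone",
                "session_noise_sd", "trait_panas_pos"} <= cols

    def test_overall_ratings_follow_time_mean_of_latent(self):
        """With zero rating noise the overall rating is the latent time mean."""
        cfg = SimulationConfig(
            n_rate=3, n_view=1, n_dance=2, n_landscape=2, rng_seed=9,
            population=constant_population(overall_noise_sd=0.0))
        ds = simulate_experiment(cfg)
        from aesthdyn.synth import (_sample_participants, _sample_stimuli)
        profs = {p.participant_id: p for p in _sample_participants(cfg)}
        stims = {s.stimulus_id: s for s in _sample_stimuli(cfg)}
        for row in ds.overall.sample(6, random_state=0).itertuples():
            latent = generate_latent_trace(profs[row.participant_id],
                                           stims[row.stimulus_id],
                                           row.session, cfg, cfg.rng_seed)
            assert row.rating == pytest.approx(float(latent.mean()))


class TestPopulationSampling:
    def test_constant_population_is_homogeneous(self):
        cfg = SimulationConfig(n_rate=3, n_view=3, n_dance=3, n_landscape=3,
                               rng_seed=1,
                               population=constant_population())
        ds = simulate_experiment(cfg)
        assert ds.participants["w_shared"].nunique() == 1
        assert ds.participants["tau_integration"].nunique() == 1

    def test_unknown_distribution_kind_raises(self):
        with pytest.raises(ValueError):
            Dist("triangular", (0, 1)).sample(np.random.default_rng(0), 3)
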
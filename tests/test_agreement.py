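"""Mean-minus-one agreement and the shared/individual variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from aesthdyn import SimulationConfig
from aesthdyn.agreement import (mm1_continuous, mm1_overall, mm1_tables,
                                variance_decomposition)
from aesthdyn.synth import generate_latent_trace, simulate_experiment
from conftest import constant_population, make_profile, make_stimulus


class TestMM1:
    def test_identical_raters_all_agree_perfectly(self, rng):
        v = rng.uniform(-1, 1, 10)
        mat = np.tile(v, (5, 1))
        assert np.allclose(mm1_overall(mat), 1.0)

    def test_contrarian_rater_scores_minus_one(self, rng):
        v = rng.uniform(-1, 1, 10)
        mat = np.vstack([np.tile(v, (4, 1)), -v])
        scores = mm1_overall(mat)
        assert scores[-1] == pytest.approx(-1.0)
        assert np.all(scores[:-1] > 0.9)

    def test_constant_rater_undefined_others_unaffected(self, rng):
        base = rng.uniform(-1, 1, (4, 12))
        mat = np.vstack([base, np.zeros(12)])
        scores = mm1_continuous(mat)
        assert np.isnan(scores[-1])
        assert not np.isnan(scores[:-1]).any()

    def test_too_few_participants_or_stimuli_raise(self, rng):
        with pytest.raises(ValueError):
            mm1_overall(rng.uniform(-1, 1, (2, 10)))
        with pytest.raises(ValueError):
            mm1_overall(rng.uniform(-1, 1, (5, 2)))

    def test_missing_cells_raise(self, rng):
        mat = rng.uniform(-1, 1, (5, 5))
        mat[2, 3] = np.nan
        with pytest.raises(ValueError):
            mm1_overall(mat)

    def test_overall_and_continuous_are_structurally_equivalent(self, rng):
        mat = rng.uniform(-1, 1, (6, 15))
        assert np.allclose(mm1_overall(mat), mm1_continuous(mat))

    def test_unshared_population_has_near_zero_agreement(self):
        """Monte-Carlo oracle: w_shared = 0 rating matrices decorrelate."""
        cfg = SimulationConfig()
        stims = [make_stimulus(stimulus_id=f"S{j:02d}") for j in range(15)]
        means = []
        for seed in range(10):
            profs = [make_profile(participant_id=f"P{i:02d}", w_shared=0.0,
                                  session_noise_sd=0.0)
                     for i in range(25)]
            mat = np.array([
                [generate_latent_trace(p, s, "test", cfg, seed=300 + seed).mean()
                 for s in stims] for p in profs])
            means.append(float(np.nanmean(mm1_overall(mat))))
        assert abs(float(np.mean(means))) < 0.1

    def test_mm1_tables_cover_the_design(self, small_dataset):
        tabs = mm1_tables(small_dataset)
        # overall MM1: every participant in every (group, session, category)
        n = small_dataset.participants.shape[0]
        assert len(tabs["overall"]) == n * 4
        # continuous MM1 exists only where continuous ratings exist
        assert not ((tabs["continuous"]["group"] == "view")
                    & (tabs["continuous"]["session"] == "test")).any()
        assert {"mean_mm1", "ci_low", "ci_high"} <= set(tabs["summary"].columns)


class TestVarianceDecomposition:
    def test_identical_everything_is_pure_shared(self, rng):
        v = rng.uniform(-1, 1, 10)
        mat = np.tile(v, (6, 1))
        d = variance_decomposition(mat, mat.copy())
        assert d.nonrepeatable_frac == pytest.approx(0.0)
        assert d.shared_frac == pytest.approx(1.0)
        assert d.individual_frac == pytest.approx(0.0)

    def test_idiosyncratic_tastes_are_individual(self):
        """Monte-Carlo oracle: independent stable tastes -> shared ~ 0."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mat = rng.uniform(-1, 1, (25, 15))
            d = variance_decomposition(mat, mat.copy())
            assert d.nonrepeatable_frac == pytest.approx(0.0)
            fracs.append(d.shared_frac)
        assert float(np.mean(fracs)) < 0.15

    def test_recovers_known_shared_fraction(self):
        """Parameter recovery at 50% shared variance (P=25, S=30)."""
        rec = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            shared = rng.normal(0, np.sqrt(0.5), 30)
            indiv = rng.normal(0, np.sqrt(0.5), (25, 30))
            x1 = shared + indiv + rng.normal(0, 0.3, (25, 30))
            x2 = shared + indiv + rng.normal(0, 0.3, (25, 30))
            d = variance_decomposition(x1, x2)
            rep = d.shared_frac + d.individual_frac
            rec.append(d.shared_frac / rep)
        assert abs(float(np.mean(rec)) - 0.5) < 0.1

    def test_invariant_to_shift_and_scale(self, rng):
        x1 = rng.uniform(-0.5, 0.5, (10, 8))
        x2 = x1 + rng.normal(0, 0.1, (10, 8))
        d0 = variance_decomposition(x1, x2)
        d1 = variance_decomposition(0.5 * x1 + 0.2, 0.5 * x2 + 0.2)
        for attr in ("nonrepeatable_frac", "shared_frac", "individual_frac"):
            assert getattr(d1, attr) == pytest.approx(getattr(d0, attr))
        assert d1.total_var == pytest.approx(0.25 * d0.total_var)

    def test_fraction_sum_is_one(self, rng):
        x1 = rng.uniform(-1, 1, (8, 8))
        x2 = rng.uniform(-1, 1, (8, 8))
        d = variance_decomposition(x1, x2)
        total = d.nonrepeatable_frac + d.shared_frac + d.individual_frac
        assert total == pytest.approx(1.0)

    def test_shape_and_size_errors(self, rng):
        with pytest.raises(ValueError):
            variance_decomposition(rng.uniform(size=(5, 5)),
                                   rng.uniform(size=(5, 4)))
        with pytest.raises(ValueError):
            variance_decomposition(np.zeros((2, 5)), np.zeros((2, 5)))
        bad = rng.uniform(size=(5, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            variance_decomposition(bad, rng.uniform(size=(5, 5)))


class TestPopulationAgreement:
    def test_fully_shared_population_has_perfect_agreement(self):
        cfg = SimulationConfig(
            n_rate=4, n_view=4, n_dance=4, n_landscape=4, rng_seed=3,
            population=constant_population(w_shared=1.0, session_noise_sd=0.0,
                                           overall_noise_sd=0.0,
                                           dead_zone=0.0))
        tabs = mm1_tables(simulate_experiment(cfg))
        assert np.allclose(tabs["overall"]["mm1"].dropna(), 1.0, atol=1e-9)
        assert np.allclose(tabs["continuous"]["mm1"].dropna(), 1.0, atol=1e-9)
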
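"""Crossed mixed models, sum contrasts, KS test, trait regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aesthdyn import SimulationConfig, ks_two_sample, simulate_experiment
from aesthdyn.inference import (LmmSpec, fit_crossed_lmm, sum_code,
                                trait_regression)


def _balanced_table(rng, n_p=12, n_s=10, category_half_diff=0.0,
                    participant_sd=0.1, stimulus_sd=0.1, resid_sd=0.3):
    rows = []
    for pi in range(n_p):
        for si in range(n_s):
            for sess in ("test", "retest"):
                rows.append({
                    "participant_id": f"P{pi:02d}",
                    "stimulus_id": ("D" if si < n_s // 2 else "L") + f"{si:02d}",
                    "category": "dance" if si < n_s // 2 else "landscape",
                    "session": sess,
                    "group": "rate" if pi < n_p // 2 else "view",
                })
    df = pd.DataFrame(rows)
    p_eff = rng.normal(0, participant_sd, n_p)
    s_eff = rng.normal(0, stimulus_sd, n_s)
    cat = sum_code(df["category"], "category")
    df["rating"] = (category_half_diff * cat
                    + p_eff[pd.factorize(df["participant_id"])[0]]
                    + s_eff[pd.factorize(df["stimulus_id"])[0]]
                    + rng.normal(0, resid_sd, len(df)))
    return df


class TestSumContrasts:
    def test_coding_is_plus_minus_one(self):
        coded = sum_code(pd.Series(["dance", "landscape", "dance"]), "category")
        assert list(coded) == [1.0, -1.0, 1.0]

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError):
            sum_code(pd.Series(["dance", "opera"]), "category")

    def test_coefficient_equals_half_cell_mean_difference(self, rng):
        """Balanced design: the sum-contrast estimate is checked against the
        direct cell-mean computation."""
        df = _balanced_table(rng, category_half_diff=0.12,
                             participant_sd=0.0, stimulus_sd=0.0,
                             resid_sd=0.05)
        spec = LmmSpec(outcome="rating", fixed_factors=("category",),
                       random_structure="intercepts_only")
        fit = fit_crossed_lmm(df, spec)
        cell = df.groupby("category")["rating"].mean()
        half_diff = (cell["dance"] - cell["landscape"]) / 2
        assert fit.coef("category") == pytest.approx(half_diff, abs=1e-3)


class TestCrossedLmm:
    def test_recovers_category_effect(self):
        """Generating half-difference falls inside the 95% CI (3 seeds)."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            df = _balanced_table(rng, category_half_diff=0.1)
            spec = LmmSpec(outcome="rating", fixed_factors=("category",),
                           random_structure="intercepts_only")
            fit = fit_crossed_lmm(df, spec)
            if abs(fit.coef("category") - 0.1) <= 1.96 * fit.se("category"):
                hits += 1
        assert hits >= 2

    def test_constant_outcome_gives_degenerate_zero_fit(self, rng):
        df = _balanced_table(rng)
        df["rating"] = 0.7
        spec = LmmSpec(outcome="rating",
                       fixed_factors=("category", "session"),
                       random_structure="overall")
        fit = fit_crossed_lmm(df, spec)
        assert fit.degenerate
        assert fit.coef("Intercept") == pytest.approx(0.7)
        assert fit.coef("category") == 0.0
        assert all(v == 0.0 for v in fit.variance_components.values())

    def test_zero_random_variance_data_yields_small_components(self):
        """With no true participant/stimulus variance the REML estimates sit
        at or near the zero boundary (the residual-sampling noise floor is
        resid/n_obs-per-level, so they cannot be exactly zero every run)."""
        n_p, n_s = 12, 10
        floors = {"participant": 1.0 / (2 * n_s), "stimulus": 1.0 / (2 * n_p)}
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = _balanced_table(rng, n_p=n_p, n_s=n_s, participant_sd=0.0,
                                 stimulus_sd=0.0, resid_sd=0.3)
            spec = LmmSpec(outcome="rating", fixed_factors=("category",),
                           random_structure="intercepts_only")
            fit = fit_crossed_lmm(df, spec)
            assert fit.converged
            for name, v in fit.variance_components.items():
                ratio = v / fit.residual_variance
                assert ratio <= 3 * floors[name]
                ratios.append(ratio)
        assert float(np.median(ratios)) <= 0.02

    def test_missing_columns_raise(self):
        spec = LmmSpec(outcome="rating", fixed_factors=("category",))
        with pytest.raises(ValueError):
            fit_crossed_lmm(pd.DataFrame({"rating": [1.0]}), spec)

    def test_unknown_random_structure_raises(self):
        with pytest.raises(ValueError):
            LmmSpec(outcome="rating", random_structure="everything")

    def test_conditional_modes_cover_levels(self, rng):
        df = _balanced_table(rng, participant_sd=0.3)
        spec = LmmSpec(outcome="rating", fixed_factors=("category",),
                       random_structure="intercepts_only")
        fit = fit_crossed_lmm(df, spec)
        assert len(fit.conditional_modes["participant"]) == 12
        assert len(fit.conditional_modes["stimulus"]) == 10
        # modes track the generating participant effects in rank order
        from scipy.stats import spearmanr
        p_eff = df.groupby("participant_id")["rating"].mean()
        rho = spearmanr(fit.conditional_modes["participant"],
                        p_eff.loc[fit.conditional_modes["participant"].index]
                        ).statistic
        assert rho > 0.9


class TestKS:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 0, 0], [1, 1, 1], 1.0),
        ([1, 2, 3, 4], [2, 3, 4, 5], 0.25),
    ])
    def test_known_values(self, a, b, expected):
        stat, p = ks_two_sample(a, b)
        assert stat == pytest.approx(expected)
        assert 0 <= p <= 1

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @staticmethod
    def _brute_force_ks(a, b):
        a, b = np.sort(a), np.sort(b)
        points = np.concatenate([a, b])
        gaps = [abs((a <= t).mean() - (b <= t).mean()) for t in points]
        return max(gaps)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50),
           st.lists(st.floats(-5, 5), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_brute_force_ecdf_oracle(self, a, b):
        stat, _ = ks_two_sample(a, b)
        assert stat == pytest.approx(self._brute_force_ks(a, b), abs=1e-12)


class TestTraitRegression:
    def test_perfect_linear_relation_gives_r2_one(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=30),
                           "x2": rng.normal(size=30)})
        df["y"] = 2.0 * df["x1"] - 0.5
        res = trait_regression(df, "y", ["x1", "x2"])
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients.loc["x1", "p"] < 1e-10

    def test_null_adjusted_r2_centers_at_zero(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(40, 4)),
                              columns=["y", "x1", "x2", "x3"])
            vals.append(trait_regression(df, "y", ["x1", "x2", "x3"]).adj_r2)
        assert abs(float(np.mean(vals))) < 0.03

    def test_rank_deficiency_raises(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=20)})
        df["x2"] = df["x1"]
        df["y"] = rng.normal(size=20)
        with pytest.raises(ValueError):
            trait_regression(df, "y", ["x1", "x2"])

    def test_constant_covariate_raises(self, rng):
        df = pd.DataFrame({"x1": np.ones(20), "y": rng.normal(size=20)})
        with pytest.raises(ValueError):
            trait_regression(df, "y", ["x1"])

    def test_generated_trait_loading_is_recovered(self):
        """Power check: the positive-affect loading on mean overall rating
        reaches significance in most simulated experiments."""
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_dance=8, n_landscape=8,
                                   rng_seed=500 + seed)
            ds = simulate_experiment(cfg)
            per_part = (ds.overall.groupby("participant_id")["rating"].mean()
                        .rename("mean_rating").reset_index()
                        .merge(ds.participants, on="participant_id"))
            res = trait_regression(
                per_part, "mean_rating",
                ["trait_panas_pos", "trait_panas_neg", "trait_stai",
                 "trait_shaps", "trait_area"])
            if (res.coefficients.loc["trait_panas_pos", "p"] < 0.05
                    and res.coefficients.loc["trait_panas_pos", "estimate"] > 0):
                hits += 1
        assert hits >= 0.8 * n_seeds
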
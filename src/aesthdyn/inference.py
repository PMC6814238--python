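"""Mixed-effects and regression analyses over the statistic tables.

Fixed factors are two-level and sum-coded (+1 / -1), so each coefficient
estimates half the difference between the two cell means in a balanced
design.  Crossed random effects (participants and stimuli) are fitted by
REML through variance components: a single grouping level spanning all rows
with indicator-coded participant / stimulus columns, plus optional
by-participant slopes (independent of the intercepts).  Significance uses
the normal-approximation criterion |t| >= 1.96 (two-tailed 5%).

Preset random structures per analysis:

* ``overall``          — participant + stimulus intercepts, by-participant
                          category slope (overall-rating model);
* ``mm1_overall``      — participant intercepts, by-participant category and
                          session slopes;
* ``mm1_continuous``   — participant + stimulus intercepts, by-participant
                          category slope;
* ``log_rmsd``         — participant + stimulus intercepts, by-participant
                          category and session slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["LmmSpec", "LmmFit", "fit_crossed_lmm", "ks_two_sample",
           "trait_regression", "sum_code", "RANDOM_STRUCTURES"]

# sum-contrast coding: first level +1, second level -1
FACTOR_LEVELS = {
    "category": ("dance", "landscape"),
    "session": ("test", "retest"),
    "group": ("rate", "view"),
}

T_CRIT = 1.96

RANDOM_STRUCTURES = {
    "overall": {"participant_intercept": True, "stimulus_intercept": True,
                "participant_slopes": ("category",)},
    "mm1_overall": {"participant_intercept": True,
                    "stimulus_intercept": False,
                    "participant_slopes": ("category", "session")},
    "mm1_continuous": {"participant_intercept": True,
                       "stimulus_intercept": True,
                       "participant_slopes": ("category",)},
    "log_rmsd": {"participant_intercept": True, "stimulus_intercept": True,
                 "participant_slopes": ("category", "session")},
    "intercepts_only": {"participant_intercept": True,
                        "stimulus_intercept": True,
                        "participant_slopes": ()},
}


def sum_code(values: pd.Series, factor: str) -> np.ndarray:
    """Map a two-level factor column onto the +1/-1 sum contrast."""
    first, second = FACTOR_LEVELS[factor]
    vals = np.asarray(values)
    unknown = set(np.unique(vals)) - {first, second}
    if unknown:
        raise ValueError(f"unknown {factor} levels: {sorted(unknown)}")
    return np.where(vals == first, 1.0, -1.0)


@dataclass
class LmmSpec:
    outcome: str
    fixed_factors: tuple[str, ...] = ("category",)
    interactions: tuple[tuple[str, ...], ...] = ()
    random_structure: str = "intercepts_only"

    def __post_init__(self) -> None:
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(
                f"unknown random_structure {self.random_structure!r}; "
                f"choose from {sorted(RANDOM_STRUCTURES)}")
        for f in self.fixed_factors:
            if f not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {f!r}")
        for term in self.interactions:
            if not set(term) <= set(self.fixed_factors):
                raise ValueError(f"interaction {term} uses unlisted factors")


@dataclass
class LmmFit:
    coefficients: pd.DataFrame      # estimate, se, t, significant per term
    variance_components: dict[str, float]
    residual_variance: float
    marginal_r2: float
    conditional_r2: float
    converged: bool
    conditional_modes: dict[str, pd.Series] = field(default_factory=dict)
    degenerate: bool = False

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])


def _fixed_design(table: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    coded = {f: sum_code(table[f], f) for f in spec.fixed_factors}
    for f in spec.fixed_factors:
        X[f] = coded[f]
    for term in spec.interactions:
        col = np.ones(len(table))
        for f in term:
            col = col * coded[f]
        X[":".join(term)] = col
    return X


def _degenerate_fit(X: pd.DataFrame, y: np.ndarray,
                    structure: dict) -> LmmFit:
    coef = pd.DataFrame(
        {"estimate": 0.0, "se": np.nan, "t": np.nan, "significant": False},
        index=X.columns)
    coef.loc["Intercept", "estimate"] = float(np.mean(y))
    vcomp = {}
    if structure["participant_intercept"]:
        vcomp["participant"] = 0.0
    if structure["stimulus_intercept"]:
        vcomp["stimulus"] = 0.0
    for f in structure["participant_slopes"]:
        vcomp[f"participant_{f}"] = 0.0
    return LmmFit(coefficients=coef, variance_components=vcomp,
                  residual_variance=0.0, marginal_r2=0.0, conditional_r2=0.0,
                  converged=True, degenerate=True)


def fit_crossed_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """REML fit of a crossed participants x stimuli mixed model.

    ``table`` must be tidy with one row per observation, containing the
    outcome column, the factor columns named in the spec, and
    ``participant_id`` / ``stimulus_id`` identifier columns (complete cases
    only).  Non-convergence is reported on the returned fit, never silently
    downgraded.
    """
    required = {spec.outcome, "participant_id", "stimulus_id",
                *spec.fixed_factors}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    table = table.dropna(subset=[spec.outcome]).reset_index(drop=True)
    y = table[spec.outcome].to_numpy(dtype=float)
    X = _fixed_design(table, spec)
    structure = RANDOM_STRUCTURES[spec.random_structure]

    if float(np.var(y)) < 1e-12:
        return _degenerate_fit(X, y, structure)

    df = table.copy()
    for f in spec.fixed_factors:
        df[f"_{f}_coded"] = sum_code(df[f], f)
    df["_group"] = 1  # single group: crossed effects via variance components

    vc_formula = {}
    if structure["participant_intercept"]:
        vc_formula["participant"] = "0 + C(participant_id)"
    if structure["stimulus_intercept"]:
        vc_formula["stimulus"] = "0 + C(stimulus_id)"
    for f in structure["participant_slopes"]:
        if f in spec.fixed_factors:
            vc_formula[f"participant_{f}"] = f"0 + C(participant_id):_{f}_coded"

    for col in X.columns:
        if col != "Intercept":
            df[f"_fx_{col.replace(':', '_x_')}"] = X[col].to_numpy()
    fixed_terms = [f"_fx_{c.replace(':', '_x_')}" for c in X.columns
                   if c != "Intercept"]
    formula = f"{spec.outcome} ~ 1"
    if fixed_terms:
        formula += " + " + " + ".join(fixed_terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups="_group",
                                     vc_formula=vc_formula, re_formula="0",
                                     data=df)
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not result.converged:
            # derivative-free restart handles boundary (zero-variance) fits
            result = model.fit(reml=True, method="powell", maxiter=500)

    name_map = {"Intercept": "Intercept"}
    for c in X.columns:
        if c != "Intercept":
            name_map[f"_fx_{c.replace(':', '_x_')}"] = c
    fe = result.fe_params.rename(name_map)
    se = result.bse_fe.rename(name_map)
    tvals = fe / se
    coef = pd.DataFrame({
        "estimate": fe, "se": se, "t": tvals,
        "significant": np.abs(tvals) >= T_CRIT,
    }).loc[list(X.columns)]

    vcomp = {name: float(v) for name, v in
             zip(model.exog_vc.names, result.vcomp)}
    resid_var = float(result.scale)

    var_fixed = float(np.var(X.to_numpy() @ fe.loc[list(X.columns)].to_numpy()))
    var_random = float(sum(vcomp.values()))
    denom = var_fixed + var_random + resid_var
    marginal = var_fixed / denom if denom > 0 else 0.0
    conditional = (var_fixed + var_random) / denom if denom > 0 else 0.0

    modes = _conditional_modes(result)
    return LmmFit(coefficients=coef, variance_components=vcomp,
                  residual_variance=resid_var, marginal_r2=marginal,
                  conditional_r2=conditional,
                  converged=bool(result.converged),
                  conditional_modes=modes)


def _conditional_modes(result) -> dict[str, pd.Series]:
    """Split the variance-component BLUPs by component name."""
    modes: dict[str, dict[str, float]] = {}
    for _grp, series in result.random_effects.items():
        for label, value in series.items():
            # labels look like "participant[C(participant_id)[P003]]"
            if "[" not in label:
                continue
            comp, rest = label.split("[", 1)
            level = rest.rsplit("[", 1)[-1].rstrip("]")
            modes.setdefault(comp.strip(), {})[level] = float(value)
    return {comp: pd.Series(vals).sort_index()
            for comp, vals in modes.items()}


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic and p-value."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    coefficients: pd.DataFrame   # estimate, se, t, p per predictor
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    n: int


def trait_regression(per_participant: pd.DataFrame, outcome: str,
                     covariates: list[str]) -> RegressionResult:
    """OLS of a per-participant outcome on standardized trait covariates.

    Predictors are z-scored (the outcome is left on its original scale), so
    coefficients are per-SD effects.  Rank deficiency raises.
    """
    df = per_participant.dropna(subset=[outcome, *covariates])
    if len(df) < len(covariates) + 2:
        raise ValueError("need at least n_covariates + 2 complete rows")
    y = df[outcome].to_numpy(dtype=float)
    Xraw = df[covariates].to_numpy(dtype=float)
    sd = Xraw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [c for c, s in zip(covariates, sd) if s == 0]
        raise ValueError(f"constant covariates: {flat}")
    Xz = (Xraw - Xraw.mean(axis=0)) / sd
    X = sm.add_constant(pd.DataFrame(Xz, columns=covariates, index=df.index))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    coef = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse, "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return RegressionResult(
        coefficients=coef, r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj), f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue), n=int(fit.nobs))
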
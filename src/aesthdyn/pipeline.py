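"""End-to-end orchestration: simulate (or load) -> analyze -> write tables.

Every stage consumes only the tidy statistic tables, so loaded real data and
simulated data follow one code path.  A machine-readable manifest (config
hash, seed, package versions, aggregated warnings) is written alongside the
outputs; together with the config it reproduces any output bit for bit.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import mm1_tables, variance_decomposition
from .config import PipelineConfig, SimulationConfig
from .dataset import Dataset, load_dataset
from .inference import LmmSpec, fit_crossed_lmm
from .reliability import reliability_summary
from .synth import simulate_experiment
from .variability import (cluster_response_styles, log_rmsd_table,
                          median_rmsd_features, reference_rmsd_logarithmic,
                          variability_table)

__all__ = ["run_pipeline", "load_dataset", "LMM_DESIGNS"]

# fixed-effect terms and random-structure preset per analysis
LMM_DESIGNS = {
    "overall": {
        "outcome": "rating",
        "factors": ("category", "session", "group"),
        "interactions": (("category", "session"), ("category", "group"),
                         ("session", "group"),
                         ("category", "session", "group")),
        "random": "overall",
    },
    "mm1_overall": {
        "outcome": "mm1",
        "factors": ("category", "session", "group"),
        "interactions": (("category", "session"), ("category", "group"),
                         ("session", "group")),
        "random": "mm1_overall",
    },
    "mm1_continuous": {
        "outcome": "mm1",
        "factors": ("category", "session", "group"),
        "interactions": (),
        "random": "mm1_continuous",
    },
    "log_rmsd": {
        "outcome": "log_rmsd",
        "factors": ("category", "group"),
        "interactions": (("category", "group"),),
        "random": "log_rmsd",
    },
}


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> dict:
    """Run the configured stages and write all outputs under ``out_dir``.

    Returns the result bundle as a dict (also useful programmatically).
    Raises on any stage error; never silently skips a configured stage.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is non-empty; pass force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    warnings_log: list[str] = []
    if dataset is None:
        dataset = simulate_experiment(config.simulation)
    dataset.write(out / "dataset", force=True)

    bundle: dict = {"dataset": dataset}

    if "reliability" in config.stages:
        rel = reliability_summary(dataset)
        _write_df(rel.records, out / "reliability_records.csv")
        _write_df(rel.per_participant, out / "reliability_per_participant.csv")
        if rel.n_dropped_pearson:
            warnings_log.append(
                f"reliability: dropped {rel.n_dropped_pearson} undefined "
                f"Pearson correlations (zero-variance traces)")
        bundle["reliability"] = rel

    if "variability" in config.stages:
        var = variability_table(dataset)
        _write_df(var, out / "variability_records.csv")
        logvar, n_zero = log_rmsd_table(var)
        if n_zero:
            warnings_log.append(
                f"variability: excluded {n_zero} zero-rmsd trials from the "
                f"log scale")
        features = median_rmsd_features(
            var[var["session"] == "retest"])
        clusters = cluster_response_styles(
            features, rng_seed=config.simulation.rng_seed)
        pd.DataFrame({
            "participant_id": clusters.labels.index,
            "cluster": clusters.labels.to_numpy(),
        }).to_csv(out / "clusters.csv", index=False)
        bundle["variability"] = var
        bundle["clusters"] = clusters
        bundle["reference_rmsd"] = reference_rmsd_logarithmic(
            config.simulation.duration_s, config.simulation.sample_rate_hz)

    if "agreement" in config.stages:
        mm1 = mm1_tables(dataset)
        _write_df(mm1["overall"], out / "mm1_overall.csv")
        _write_df(mm1["continuous"], out / "mm1_continuous.csv")
        _write_df(mm1["summary"], out / "mm1_summary.csv")
        decomp = {}
        for (group, cat), grp in dataset.overall.groupby(
                ["group", "category"]):
            mats = {
                sess: g.pivot(index="participant_id", columns="stimulus_id",
                              values="rating")
                for sess, g in grp.groupby("session")
            }
            d = variance_decomposition(mats["test"], mats["retest"])
            if d.n_clipped:
                warnings_log.append(
                    f"agreement: clipped {d.n_clipped} negative variance "
                    f"estimates for {group}/{cat}")
            decomp[f"{group}/{cat}"] = {
                "total_var": d.total_var,
                "nonrepeatable_frac": d.nonrepeatable_frac,
                "shared_frac": d.shared_frac,
                "individual_frac": d.individual_frac,
                **{f"component_{k}": v for k, v in d.components.items()},
            }
        with open(out / "variance_decomposition.json", "w") as fh:
            json.dump(decomp, fh, indent=2, sort_keys=True)
        bundle["mm1"] = mm1
        bundle["decomposition"] = decomp

    if "inference" in config.stages:
        fits = {}
        tables = _lmm_tables(dataset, bundle)
        for name, design in LMM_DESIGNS.items():
            table = tables.get(name)
            if table is None or not len(table):
                continue
            spec = LmmSpec(outcome=design["outcome"],
                           fixed_factors=design["factors"],
                           interactions=design["interactions"],
                           random_structure=design["random"])
            fit = fit_crossed_lmm(table, spec)
            if not fit.converged:
                warnings_log.append(f"inference: LMM {name} did not converge")
            fits[name] = fit
            fit.coefficients.to_csv(out / f"lmm_{name}_coefficients.csv",
                                    float_format="%.10g")
            with open(out / f"lmm_{name}_variance.json", "w") as fh:
                json.dump({
                    "variance_components": fit.variance_components,
                    "residual_variance": fit.residual_variance,
                    "marginal_r2": fit.marginal_r2,
                    "conditional_r2": fit.conditional_r2,
                    "converged": fit.converged,
                }, fh, indent=2, sort_keys=True)
        bundle["lmm_fits"] = fits

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_digest": config.simulation.digest(),
        "rng_seed": config.simulation.rng_seed,
        "stages": list(config.stages),
        "warnings": warnings_log,
        "n_event_rows": int(len(dataset.events)),
        "n_overall_rows": int(len(dataset.overall)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _lmm_tables(dataset: Dataset, bundle: dict) -> dict[str, pd.DataFrame]:
    """Statistic tables feeding each mixed-model design."""
    tables: dict[str, pd.DataFrame] = {}
    tables["overall"] = dataset.overall.rename(columns={})
    mm1 = bundle.get("mm1")
    if mm1 is None:
        mm1 = mm1_tables(dataset)
    ov = mm1["overall"].copy()
    ov["stimulus_id"] = "all"  # MM1-overall has no stimulus granularity
    tables["mm1_overall"] = ov.dropna(subset=["mm1"])
    tables["mm1_continuous"] = mm1["continuous"].dropna(subset=["mm1"])
    var = bundle.get("variability")
    if var is None:
        var = variability_table(dataset)
    logvar, _ = log_rmsd_table(var[var["session"] == "retest"])
    tables["log_rmsd"] = logvar
    return tables
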
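"""Trait and category-preference regressions on per-observer summaries.

Regresses mean overall ratings and mean rmsd on the mood/trait covariates
(PANAS, STAI, SHAPS, AREA stand-ins), and runs the single-predictor
category-preference regressions (does self-reported landscape liking predict
mean landscape ratings, etc.).
"""

import argparse
from pathlib import Path

from aesthdyn.dataset import Dataset
from aesthdyn.inference import trait_regression
from aesthdyn.variability import variability_table

TRAITS = ["trait_panas_pos", "trait_panas_neg", "trait_stai",
          "trait_shaps", "trait_area"]


def report(title, res, focus):
    row = res.coefficients.loc[focus]
    print(f"{title}: R2 = {res.r2:.2f} (adj {res.adj_r2:.2f}), "
          f"F = {res.f_stat:.2f} (p = {res.f_pvalue:.3f}); "
          f"{focus}: B = {row['estimate']:+.3f}, t = {row['t']:+.2f}, "
          f"p = {row['p']:.3f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = Dataset.read(args.out / "dataset")
    per = ds.participants.set_index("participant_id").copy()
    per["mean_rating"] = ds.overall.groupby("participant_id")["rating"].mean()
    var = variability_table(ds)
    per["mean_rmsd"] = var.groupby("participant_id")["rmsd"].mean()
    for cat in ("dance", "landscape"):
        sel = ds.overall[ds.overall["category"] == cat]
        per[f"mean_rating_{cat}"] = sel.groupby("participant_id")["rating"].mean()
        per[f"mean_rmsd_{cat}"] = (var[var["category"] == cat]
                                   .groupby("participant_id")["rmsd"].mean())

    res = trait_regression(per, "mean_rating", TRAITS)
    report("overall ratings ~ traits", res, "trait_panas_pos")
    res.coefficients.to_csv(args.out / "regression_rating_traits.csv")

    res = trait_regression(per, "mean_rmsd", TRAITS)
    report("mean rmsd ~ traits", res, "trait_shaps")
    res.coefficients.to_csv(args.out / "regression_rmsd_traits.csv")

    for cat in ("dance", "landscape"):
        res = trait_regression(per, f"mean_rating_{cat}", [f"trait_pref_{cat}"])
        report(f"{cat} ratings ~ {cat} preference", res, f"trait_pref_{cat}")
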
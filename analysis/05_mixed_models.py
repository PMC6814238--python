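"""Crossed mixed-effects models over the statistic tables.

Four REML fits with sum-coded two-level factors (so a coefficient is half
the cell-mean difference): overall ratings, MM1 for overall ratings, MM1
for continuous ratings, and log-rmsd (retest session).  Significance uses
the |t| >= 1.96 two-tailed criterion.
"""

import argparse
import json
from pathlib import Path

from aesthdyn.dataset import Dataset
from aesthdyn.inference import LmmSpec, fit_crossed_lmm
from aesthdyn.pipeline import LMM_DESIGNS, _lmm_tables

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = Dataset.read(args.out / "dataset")
    tables = _lmm_tables(ds, {})
    for name, design in LMM_DESIGNS.items():
        spec = LmmSpec(outcome=design["outcome"],
                       fixed_factors=design["factors"],
                       interactions=design["interactions"],
                       random_structure=design["random"])
        fit = fit_crossed_lmm(tables[name], spec)
        fit.coefficients.to_csv(args.out / f"lmm_{name}_coefficients.csv",
                                float_format="%.10g")
        with open(args.out / f"lmm_{name}_variance.json", "w") as fh:
            json.dump({"variance_components": fit.variance_components,
                       "residual_variance": fit.residual_variance,
                       "marginal_r2": fit.marginal_r2,
                       "conditional_r2": fit.conditional_r2}, fh, indent=2)
        print(f"\n{name} (n = {len(tables[name])}, "
              f"converged = {fit.converged}, "
              f"R2 marginal/conditional = {fit.marginal_r2:.3f}/"
              f"{fit.conditional_r2:.3f})")
        for term, row in fit.coefficients.iterrows():
            star = " *" if row["significant"] else ""
            print(f"  {term:<28} B = {row['estimate']:+.3f} "
                  f"(SE {row['se']:.3f}, t = {row['t']:+.2f}){star}")
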
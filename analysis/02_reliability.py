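"""Test-retest reliability of continuous traces and overall judgments.

Computes, for every rate-group (observer, clip) pair, the Pearson r and the
scaled-L2 score between the test and retest trace; summarizes per observer
and category; and correlates overall-rating reliability with continuous
reliability across observers.
"""

import argparse
from pathlib import Path

from aesthdyn.dataset import Dataset
from aesthdyn.reliability import reliability_summary
from aesthdyn.timeseries import fisher_mean_ci

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = Dataset.read(args.out / "dataset")
    rel = reliability_summary(ds)
    rel.records.to_csv(args.out / "reliability_records.csv", index=False)
    rel.per_participant.to_csv(args.out / "reliability_per_participant.csv",
                               index=False)

    for cat, grp in rel.per_participant.groupby("category"):
        fm = fisher_mean_ci(grp["mean_pearson"].dropna())
        print(f"{cat:>9}: mean Pearson r = {fm.mean_r:.2f} "
              f"[{fm.ci_low:.2f}, {fm.ci_high:.2f}], "
              f"mean L2 = {grp['mean_l2'].mean():.2f}")
    for cat, r in rel.cross_measure.items():
        print(f"{cat:>9}: r(overall L2, median continuous L2) = {r:.2f}")
    stat, p = rel.wilcoxon["pearson"]
    print(f"category difference (Wilcoxon on per-observer mean r): "
          f"W = {stat:.0f}, p = {p:.3f}")
    if rel.n_dropped_pearson:
        print(f"dropped {rel.n_dropped_pearson} undefined correlations")
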
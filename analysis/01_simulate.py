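"""Simulate the full experiment and write the dataset tables.

Design: 25 *rate* + 25 *view* observers, 15 dance + 15 landscape 30-s clips,
test and retest sessions; continuous dial ratings at 10 Hz for the rate
group in both sessions and the view group at retest only; overall judgments
for everyone.  Run me first; the later scripts read results/dataset.
"""

import argparse
from pathlib import Path

from aesthdyn import SimulationConfig, simulate_experiment

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(rng_seed=args.seed)
    ds = simulate_experiment(cfg)
    ds.write(args.out / "dataset", force=True)

    n_trials = ds.traces().shape[0]
    print(f"simulated {len(ds.participants)} observers x "
          f"{len(ds.stimuli)} clips x 2 sessions")
    print(f"  overall ratings : {len(ds.overall)} rows")
    print(f"  continuous trials: {n_trials} "
          f"({len(ds.events)} dial events)")
    means = ds.overall.groupby("category")["rating"].mean()
    print(f"  mean overall rating  dance={means['dance']:+.3f}  "
          f"landscape={means['landscape']:+.3f}")
    print(f"dataset written to {args.out / 'dataset'}")
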
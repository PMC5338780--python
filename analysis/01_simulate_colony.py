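"""Simulate the study colony and write the raw data files.

A dozen chick-rearing birds carrying GPS (1-min fixes) and 1-Hz depth
loggers, 4-10 trips each, plus isotope and regurgitate samples, with the
ground-truth parameter table kept alongside for later comparison.
"""

import argparse
from pathlib import Path

import foragespec as fs
from foragespec import io as fio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = fs.SimConfig(seed=args.seed)
deployments, depth_frames, iso, diets, truth = fs.simulate_population(cfg)

args.out.mkdir(parents=True, exist_ok=True)
fio.write_gps_csv(deployments, args.out / "gps.csv")
fio.write_tdr_csv(depth_frames, args.out / "tdr.csv")
iso.to_csv(args.out / "isotopes.csv", index=False, float_format="%.6f")
diets.to_csv(args.out / "diet.csv", index=False)
truth.individuals.to_csv(args.out / "truth_individuals.csv", index=False,
                         float_format="%.6f")
truth.trip_counts.to_csv(args.out / "truth_trip_counts.csv", index=False)
truth.dives.to_csv(args.out / "truth_dives.csv", index=False,
                   float_format="%.3f")

n_fixes = sum(len(d.fixes) for d in deployments)
print(f"simulated {cfg.n_individuals} individuals, "
      f"{truth.trip_counts['n_trips'].sum()} trips, {n_fixes} GPS fixes, "
      f"{len(truth.dives)} scheduled dives -> {args.out}")
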
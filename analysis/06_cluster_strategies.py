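"""Group individual profiles into foraging strategies.

Ward clustering (Euclidean distance, heights as within-SS increase) on the
standardized spatial means and CVs, with the cluster count chosen at the
largest relative merge-height jump; cluster-level profiles are then
summarised and dive depth compared across clusters.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import foragespec as fs
from foragespec.cluster import DEFAULT_FEATURES

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
parser.add_argument("--k", type=int, default=None,
                    help="fix the cluster count instead of choosing it")
args = parser.parse_args()

profiles = pd.read_csv(args.out / "profiles.csv", na_values="NA")
feats = profiles.dropna(subset=["consistency_index"]).reset_index(drop=True)
cols = ["mean_heading_deg"] + [c for c in DEFAULT_FEATURES if c in feats]
sol = fs.cluster_profiles(feats[cols], k=args.k)

clusters = feats[["individual_id", "stage"]].copy()
clusters["cluster"] = sol.labels
clusters.to_csv(args.out / "clusters.csv", index=False)

print(f"{len(feats)} profiles grouped into k = {sol.k} strategies")
summary = (feats.assign(cluster=sol.labels)
           .groupby("cluster")[["mean_total_distance_km", "mean_heading_deg",
                                "consistency_index", "sd_heading"]]
           .agg(["mean", "sem"]))
summary.to_csv(args.out / "cluster_profiles.csv", float_format="%.3f")
print(summary.round(2).to_string())

depth = feats["mean_max_depth_m"]
if depth.notna().sum() >= 4 and len(set(sol.labels[depth.notna()])) >= 2:
    mask = depth.notna().to_numpy()
    res = fs.compare_clusters(sol.labels[mask], depth[mask].to_numpy(),
                              feats.loc[mask, "individual_id"].to_numpy())
    print(f"dive depth vs cluster: LR = {res['lr']:.2f}, p = {res['p']:.3f}")
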
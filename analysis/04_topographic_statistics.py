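#!/usr/bin/env python
"""Topographic statistics: TCT gate, TANCOVA, GFP covariation, windows.

Loads the simulated cohort ERPs and the behaviourally estimated d', then
follows the study's analysis order: the topographic consistency test first
(analyses are restricted to frames with consistent topographies), then the
TANCOVA on GFP=1-normalized maps and the GFP covariation analysis, each
with a permutation null; significant frames are kept only in runs of at
least 20 ms; long GFP windows are subdivided into ~70 ms sub-windows at
effect-size maxima and merged back when their covariance maps are
spatially similar (r >= 0.9).

Writes results/topostats/: per-frame CSVs, windows.json and one
covariance-map CSV per retained window.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from topolearn.datasets import CovariateSeries, load_erp_dataset
from topolearn.topostats import (
    gfp_covariation,
    significant_windows,
    subdivide_and_merge,
    tancova,
    tct,
    window_covariance_map,
)

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--behavior", type=Path, default=Path("results/behavior.csv"))
parser.add_argument("--out", type=Path, default=Path("results/topostats"))
parser.add_argument("--n-perm", type=int, default=1000)
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

erps = load_erp_dataset(args.cohort / "erps")
scores = pd.read_csv(args.behavior)
covariate = CovariateSeries(
    tuple(scores["subject_id"]), scores["dprime"].to_numpy()
).aligned_to(erps.subject_ids)

args.out.mkdir(parents=True, exist_ok=True)

consistency = tct(erps, n_perm=args.n_perm, seed=args.seed)
frames = consistency.significant(0.05)
print(f"TCT: consistent topographies at {frames.mean():.0%} of timeframes")

tanc = tancova(erps, covariate, n_perm=args.n_perm, seed=args.seed + 1,
               frames=frames)
gfpc = gfp_covariation(erps, covariate, n_perm=args.n_perm,
                       seed=args.seed + 2, frames=frames)

windows = {}
for name, res in (("tancova", tanc), ("gfp", gfpc)):
    pd.DataFrame(
        {"time_ms": res.times_ms, "effect": res.effect, "p": res.p}
    ).to_csv(args.out / f"{name}.csv", index=False)
    wins = list(significant_windows(res))
    windows[name] = [list(w) for w in wins]
    print(f"{name}: significant windows "
          + (", ".join(f"{a:.0f}-{b:.0f} ms" for a, b in wins) or "none"))

# subdivide long GFP windows and merge spatially similar sub-windows
merged = []
for w in windows["gfp"]:
    merged.extend(subdivide_and_merge(gfpc, erps, covariate, tuple(w)))
windows["gfp_subdivided"] = [list(w) for w, _ in merged]
if merged:
    print("gfp sub-windows after merge: "
          + ", ".join(f"{a:.0f}-{b:.0f} ms" for (a, b), _ in merged))

(args.out / "windows.json").write_text(json.dumps(windows, indent=2))

all_maps = [
    (tuple(w), window_covariance_map(erps, covariate, tuple(w)))
    for w in windows["tancova"]
] + merged
for (a, b), cmap in all_maps:
    path = args.out / f"covariance_map_{a:.0f}-{b:.0f}ms.csv"
    pd.DataFrame(
        {"electrode": erps.montage.names, "value": cmap.values}
    ).to_csv(path, index=False)
    ex_max = cmap.values.argmax()
    ex_min = cmap.values.argmin()
    print(f"map {a:.0f}-{b:.0f} ms: max {cmap.values[ex_max]:+.2f} at "
          f"{erps.montage.names[ex_max]}, min {cmap.values[ex_min]:+.2f} at "
          f"{erps.montage.names[ex_min]} (GFP {cmap.gfp:.2f})")
print(f"wrote {args.out}")
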
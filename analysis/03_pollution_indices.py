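#!/usr/bin/env python
"""Pollution indices Cf, Igeo, EF, PLI, NPI with class distributions.

On the survey emulation, Cd is the only element with moderate
contamination at the mean, most orchards sit at baseline overall
pollution (PLI < 1), and Cd shows significant enrichment in most
orchards — the survey's qualitative picture.
"""
import argparse
from pathlib import Path

import pandas as pd

import soiltrace as st
from soiltrace.pollution import long_format

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

table = st.emulate_study(seed=args.seed)
rep = st.pollution_report(table)

long_format(rep["elementwise"], rep["labels"]).to_csv(
    args.outdir / "pollution_indices_long.csv", index=False, float_format="%.4g"
)
dists = []
for name, d in rep["distributions"].items():
    d = d.copy()
    d.insert(0, "index", name)
    d.insert(1, "class", d.index)
    dists.append(d.reset_index(drop=True))
pd.concat(dists, ignore_index=True).to_csv(
    args.outdir / "pollution_class_distribution.csv", index=False, float_format="%.2f"
)

print("mean Cf:", rep["mean_index"]["Cf"].round(2).to_dict())
print(f"mean PLI = {rep['mean_index']['PLI']:.3f}  (baseline if < 1)")
print(f"mean NPI = {rep['mean_index']['NPI']:.3f}")
cd_ef = rep["distributions"]["EF"]["Cd"]
print(f"Cd 'Significant enrichment' share: {cd_ef.get('Significant enrichment', 0.0):.1f}%")
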
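#!/usr/bin/env python
"""APCS-MLR source apportionment and the recovery experiment.

Fits the receptor model to the survey emulation (three components, as in
the survey) and then scores recovery on 20 fresh mixing tables with
known ground truth: dominant-source identification and mean absolute
error of the contribution percentages.
"""
import argparse
import warnings
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

import soiltrace as st

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

table = st.emulate_study(seed=args.seed)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = st.run_apcs_mlr(table)
model.summary().to_csv(args.outdir / "apcs_summary.csv", float_format="%.4g")
print(f"emulation: {model.fit.n_components} components, "
      f"KMO = {model.fit.kmo:.3f}, variance explained {model.fit.variance_explained.sum():.1f}%")
print("M/P ratios all 1:", bool(np.allclose(model.mp_ratio, 1.0, atol=1e-9)))
print("mean source contributions (%):", model.mean_contribution_pct.round(1).to_dict())

rows = []
for seed in range(args.seed, args.seed + 20):
    mixing, truth = st.generate_mixing(129, 3, seed=seed, noise_cv=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = st.run_apcs_mlr(mixing, n_components=3)
    est, tru = fit.contribution_pct.to_numpy(), truth.true_contribution_pct.to_numpy()
    mae, perm = min(
        (float(np.abs(est[:, list(p)] - tru).mean()), p) for p in permutations(range(3))
    )
    dom = int((est[:, list(perm)].argmax(1) == tru.argmax(1)).sum())
    rows.append({"seed": seed, "mae_points": mae, "dominant_correct": dom})
rec = pd.DataFrame(rows)
rec.to_csv(args.outdir / "recovery_experiment.csv", index=False, float_format="%.3f")
print(f"recovery over 20 seeds: MAE {rec.mae_points.mean():.2f} points "
      f"(max {rec.mae_points.max():.2f}), dominant source "
      f"{rec.dominant_correct.min()}-{rec.dominant_correct.max()}/10 correct")
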
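#!/usr/bin/env python
"""Ecological risk: worked examples from published means, then the
per-orchard Er/RI/NRI panorama on the survey emulation.

The worked examples use the linearity of Cf/Er/RI: mean index values
follow directly from the published mean concentrations and the packaged
UCC backgrounds and toxicity coefficients.
"""
import argparse
from pathlib import Path

import pandas as pd

import soiltrace as st

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

stats, n = st.load_survey_summary()
ref = st.default_reference_set()
er = {}
for el in st.TR_ELEMENTS:
    cf = st.contamination_factor(stats.loc[el, "mean"], ref.background[el])
    er[el] = st.ecological_risk_factor(round(cf, 2) if el == "Cd" else cf, ref.tr[el])
shares = st.ri_contributions(er)
worked = pd.DataFrame({"mean_Er": er, "RI_share_pct": shares})
worked.to_csv(args.outdir / "ecorisk_worked_examples.csv", float_format="%.4g")
print("mean Er from published means:", {k: round(float(v), 2) for k, v in er.items()})
print(f"mean RI = {st.risk_index(er):.1f}; Cd share = {shares['Cd']:.1f}%")

table = st.emulate_study(seed=args.seed)
rep = st.ecological_risk_report(table)
rep["distributions"]["Er"].to_csv(args.outdir / "er_class_distribution.csv", float_format="%.2f")
print(f"emulation: mean RI = {rep['mean_ri']:.1f}, mean NRI = {rep['mean_nri']:.1f}")
print("Cd Er classes (%):", rep["distributions"]["Er"]["Cd"].round(1).to_dict())
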
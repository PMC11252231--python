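"""One-call orchestration: table -> stats -> indices -> risks -> sources.

``run_full_analysis`` reads (or simulates) a sample table, runs every
stage, and writes a report bundle to the output directory:

* ``summary_stats.csv``       — per-element descriptive statistics
* ``class_distributions.csv`` — per-index class percentages over sites
* ``ecological_risk.csv``     — mean Er / RI shares per element
* ``health_risk_hq.csv``      — HQ per element x route x receptor
* ``health_risk_cr.csv``      — carcinogenic risk per element x route
* ``apcs_summary.csv``        — receptor-model table (M, P, M/P, R2, %)
* ``headline.json``           — scalar headlines (mean PLI/NPI/RI, THI, CTCR, ...)
* ``warnings.log``            — everything the stages warned about

Reports round floats to 4 significant digits for stable snapshots;
``headline_full.json`` keeps full precision for auditing. Same config and
seed give a byte-identical bundle.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import apcs, descriptive, ecorisk, health, pollution, simulate
from .reference_data import (
    SampleTable,
    default_reference_set,
    default_schemes,
    read_sample_table,
)

log = logging.getLogger("soiltrace")


@dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    input: str | None = None          # CSV path; None -> simulate the survey emulation
    outdir: str = "soiltrace_out"
    elements: list[str] | None = None
    reference_path: str | None = None
    toxicity_path: str | None = None
    alpha: float = 0.05
    eigenvalue_threshold: float = 1.0
    ref_element: str = "Al"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _fmt(df: pd.DataFrame | pd.Series, path: Path) -> None:
    frame = df.to_frame() if isinstance(df, pd.Series) else df
    frame.to_csv(path, float_format="%.4g")


def run_full_analysis(config: RunConfig, table: SampleTable | None = None) -> dict:
    """Run every stage and write the report bundle; returns paths + headlines."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []

    if table is None:
        if config.input is None:
            table = simulate.emulate_study(seed=config.seed)
        else:
            table = read_sample_table(config.input, elements=config.elements)
    elif config.elements is not None:
        table = table.restrict(config.elements)

    refset = default_reference_set(config.reference_path)
    schemes = default_schemes()
    headline: dict = {"n_sites": table.n_sites, "elements": table.elements}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # --- descriptive statistics ---------------------------------------
        stats = descriptive.summarize(table)
        _fmt(stats, outdir / "summary_stats.csv")
        if len(table.elements) >= 2 and table.n_sites >= 4:
            corr = descriptive.spearman_matrix(table)
            _fmt(corr.r, outdir / "spearman_r.csv")
        normal = descriptive.normality_flags(table, alpha=config.alpha)
        headline["normal_elements"] = [el for el, ok in normal.items() if ok]

        # --- pollution indices --------------------------------------------
        pol = pollution.pollution_report(
            table, refset=refset, ref_element=config.ref_element, schemes=schemes
        )
        dist_frames = []
        for name, dist in pol["distributions"].items():
            d = dist.copy()
            d.insert(0, "index", name)
            d.insert(1, "class", d.index)
            dist_frames.append(d.reset_index(drop=True))
        headline["mean_PLI"] = pol["mean_index"]["PLI"]
        headline["mean_NPI"] = pol["mean_index"]["NPI"]
        headline["mean_Cf"] = pol["mean_index"]["Cf"].to_dict()

        # --- ecological risk ----------------------------------------------
        try:
            eco = ecorisk.ecological_risk_report(table, refset=refset, schemes=schemes)
            for name, dist in eco["distributions"].items():
                d = dist.copy()
                d.insert(0, "index", name)
                d.insert(1, "class", d.index)
                dist_frames.append(d.reset_index(drop=True))
            _fmt(
                pd.DataFrame(
                    {"mean_Er": eco["mean_er"], "RI_share_pct": eco["contribution_pct"]}
                ),
                outdir / "ecological_risk.csv",
            )
            headline["mean_RI"] = eco["mean_ri"]
            headline["mean_NRI"] = eco["mean_nri"]
        except ValueError as exc:
            warnings.warn(f"ecological risk skipped: {exc}")
        _fmt(pd.concat(dist_frames, ignore_index=True), outdir / "class_distributions.csv")

        # --- health risk ----------------------------------------------------
        risk = health.aggregate_risks(table.data.mean())
        tables = health.risk_tables(risk)
        _fmt(tables["hq_long"].set_index("element"), outdir / "health_risk_hq.csv")
        _fmt(tables["carcinogenic"], outdir / "health_risk_cr.csv")
        headline["THI"] = risk.thi
        headline["CTCR"] = risk.ctcr

        # --- source apportionment ------------------------------------------
        if len(table.elements) >= 2 and table.n_sites >= 4:
            try:
                model = apcs.run_apcs_mlr(
                    table, eigenvalue_threshold=config.eigenvalue_threshold
                )
                _fmt(model.summary(), outdir / "apcs_summary.csv")
                _fmt(model.fit.loadings, outdir / "apcs_loadings.csv")
                _fmt(model.apcs, outdir / "apcs_scores.csv")
                headline["n_components"] = model.fit.n_components
                headline["KMO"] = model.fit.kmo
                headline["variance_explained_pct"] = float(
                    model.fit.variance_explained.sum()
                )
                headline["mean_source_contribution_pct"] = (
                    model.mean_contribution_pct.to_dict()
                )
            except ValueError as exc:
                warnings.warn(f"APCS-MLR stage skipped: {exc}")
        else:
            warnings.warn("APCS-MLR stage skipped: table too small for factor analysis")

        captured = [str(w.message) for w in wlist]

    (outdir / "warnings.log").write_text("\n".join(captured) + "\n" if captured else "")
    with open(outdir / "headline_full.json", "w") as fh:
        json.dump(headline, fh, indent=1, sort_keys=True)
    rounded = json.loads(
        json.dumps(headline), parse_float=lambda s: float(f"{float(s):.4g}")
    )
    with open(outdir / "headline.json", "w") as fh:
        json.dump(rounded, fh, indent=1, sort_keys=True)
    for msg in captured:
        log.warning(msg)
    return {"outdir": str(outdir), "headline": headline, "warnings": captured}
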
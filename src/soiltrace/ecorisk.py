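"""Hakanson ecological risk: Er per element, RI and NRI per site.

Only the six elements with defined toxicity response coefficients
(Zn, Cu, Cd, Ni, Cr, Pb) enter Er/RI/NRI; Al, Co, Fe and Mn are excluded
by construction. RI is the plain sum of the six Er values, so the mean RI
over sites equals the sum of the mean Er values exactly; NRI combines the
mean and the maximum Er of each site and is nonlinear.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .reference_data import (
    ClassificationScheme,
    ReferenceSet,
    SampleTable,
    default_reference_set,
    default_schemes,
)
from .pollution import classify_matrix, class_distribution, contamination_factor

#: Elements carrying a Hakanson toxicity response coefficient.
TR_ELEMENTS = ("Zn", "Cu", "Cd", "Ni", "Cr", "Pb")


def ecological_risk_factor(cf, tr: float):
    """Er = Tr * Cf for one element."""
    if tr is None:
        raise ValueError("no toxicity coefficient for this element")
    return tr * cf


def risk_index(er_values: Mapping[str, float] | pd.Series) -> float:
    """RI = sum of Er over exactly the six Tr-bearing elements."""
    er = pd.Series(dict(er_values))
    missing = [e for e in TR_ELEMENTS if e not in er.index]
    if missing:
        raise ValueError(f"RI requires all six Tr elements; missing {missing}")
    return float(er[list(TR_ELEMENTS)].sum())


def nemerow_risk_index(er_values) -> float:
    """NRI = sqrt((Er_mean^2 + Er_max^2) / 2) over one sample's Er vector."""
    er = np.asarray(
        er_values if not isinstance(er_values, (pd.Series, dict)) else pd.Series(er_values),
        dtype=float,
    )
    if er.size == 0:
        raise ValueError("empty Er vector")
    return float(np.sqrt((np.mean(er) ** 2 + np.max(er) ** 2) / 2.0))


def ri_contributions(er_means: Mapping[str, float] | pd.Series) -> pd.Series:
    """Percent share of each element's mean Er in the mean RI."""
    er = pd.Series(dict(er_means)).astype(float)
    total = er.sum()
    if not (total > 0):
        raise ValueError("total Er must be > 0")
    return 100.0 * er / total


def ecological_risk_report(
    table: SampleTable,
    refset: ReferenceSet | None = None,
    schemes: Mapping[str, ClassificationScheme] | None = None,
) -> dict:
    """Per-site Er/RI/NRI with class labels, distributions and RI shares."""
    refset = refset if refset is not None else default_reference_set()
    schemes = dict(schemes) if schemes is not None else default_schemes()
    elements = [e for e in TR_ELEMENTS if e in table.elements]
    missing = [e for e in TR_ELEMENTS if e not in table.elements]
    if missing:
        raise ValueError(f"table lacks Tr elements {missing}")
    er = pd.DataFrame(
        {
            el: ecological_risk_factor(
                contamination_factor(table.column(el), refset.background[el]),
                refset.tr[el],
            )
            for el in elements
        }
    )
    ri = er.sum(axis=1)
    nri = er.apply(lambda row: nemerow_risk_index(row.to_numpy()), axis=1)
    er_labels = classify_matrix(er, schemes["Er"])
    ri_labels = classify_matrix(ri, schemes["RI"])
    nri_labels = classify_matrix(nri, schemes["NRI"])
    mean_er = er.mean()
    return {
        "er": er,
        "ri": ri,
        "nri": nri,
        "labels": {"Er": er_labels, "RI": ri_labels, "NRI": nri_labels},
        "distributions": {
            "Er": pd.DataFrame(
                {el: class_distribution(er_labels[el], schemes["Er"]) for el in elements}
            ),
            "RI": class_distribution(ri_labels, schemes["RI"]).to_frame("RI"),
            "NRI": class_distribution(nri_labels, schemes["NRI"]).to_frame("NRI"),
        },
        "mean_er": mean_er,
        "mean_ri": float(ri.mean()),
        "mean_nri": float(nri.mean()),
        "contribution_pct": ri_contributions(mean_er),
    }
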
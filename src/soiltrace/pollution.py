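"""Soil pollution indices: Cf, Igeo, EF (per element) and PLI, NPI (per site).

All five indices are computed per sample and then aggregated, so the class
distribution over sites is available for every index; the headline "mean
index" is the mean of the per-sample values. For the linear contamination
factor the mean over samples equals (mean concentration)/background, which
is what licenses worked examples computed directly from published mean
concentrations; the nonlinear Igeo/EF/PLI/NPI enjoy no such shortcut.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_data import (
    ClassificationScheme,
    ReferenceSet,
    SampleTable,
    default_reference_set,
    default_schemes,
)

ArrayLike = "float | np.ndarray | pd.Series"


def contamination_factor(conc, background: float):
    """Cf = C / C_background (dimensionless, > 0)."""
    if not (background > 0):
        raise ValueError("background must be > 0")
    return conc / background


def geoaccumulation_index(conc, background: float):
    """Igeo = log2(C / (1.5 * background)).

    The factor 1.5 absorbs lithogenic variability of the background; Igeo
    <= 0 is unpolluted.
    """
    if not (background > 0):
        raise ValueError("background must be > 0")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    out = np.log2(conc / (1.5 * background))
    return out.item() if out.ndim == 0 else out


def enrichment_factor(conc, ref_conc, background: float, ref_background: float):
    """EF = (C/C_ref)_sample / (C/C_ref)_background.

    ``ref`` is the conservative reference element used for geochemical
    normalization (Al by default in this package).
    """
    for v, name in ((background, "background"), (ref_background, "ref background")):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0")
    conc = np.asarray(conc, dtype=float)
    ref_conc = np.asarray(ref_conc, dtype=float)
    if np.any(conc <= 0) or np.any(ref_conc <= 0):
        raise ValueError("concentrations must be > 0")
    out = (conc / ref_conc) / (background / ref_background)
    return out.item() if out.ndim == 0 else out


def pollution_load_index(cf_values) -> float:
    """PLI = geometric mean of the per-element Cf values of one sample."""
    cf = np.asarray(cf_values, dtype=float)
    if cf.size == 0:
        raise ValueError("empty Cf vector")
    if np.any(cf <= 0):
        raise ValueError("all Cf must be > 0")
    return float(np.exp(np.mean(np.log(cf))))


def nemerow_pollution_index(cf_values) -> float:
    """NPI = sqrt((Cf_mean^2 + Cf_max^2) / 2) over one sample's Cf vector."""
    cf = np.asarray(cf_values, dtype=float)
    if cf.size == 0:
        raise ValueError("empty Cf vector")
    return float(np.sqrt((np.mean(cf) ** 2 + np.max(cf) ** 2) / 2.0))


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Class label for one index value under ``scheme``."""
    return scheme.classify(value)


def class_distribution(labels: Sequence[str], scheme: ClassificationScheme) -> pd.Series:
    """Percentage of sites per class, zero-count classes included."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels")
    counts = pd.Series(0.0, index=list(scheme.labels))
    vc = pd.Series(labels).value_counts()
    unknown = set(vc.index) - set(scheme.labels)
    if unknown:
        raise ValueError(f"labels not in scheme {scheme.name!r}: {sorted(unknown)}")
    counts.loc[vc.index] = vc.values
    return 100.0 * counts / len(labels)


# ---------------------------------------------------------------------------
# Whole-table drivers
# ---------------------------------------------------------------------------

def elementwise_indices(
    table: SampleTable,
    refset: ReferenceSet | None = None,
    ref_element: str = "Al",
) -> dict[str, pd.DataFrame]:
    """Per-sample Cf, Igeo and EF matrices (site x element).

    EF for the reference element itself is identically 1 and is included
    for completeness.
    """
    refset = refset if refset is not None else default_reference_set()
    bg = refset.background
    missing = [e for e in table.elements if e not in bg]
    if missing:
        raise ValueError(f"no background value for elements: {missing}")
    conc = table.data
    cf = pd.DataFrame(
        {el: contamination_factor(conc[el], bg[el]) for el in table.elements}
    )
    igeo = pd.DataFrame(
        {el: geoaccumulation_index(conc[el], bg[el]) for el in table.elements}
    )
    out = {"Cf": cf, "Igeo": igeo}
    if ref_element in table.elements:
        out["EF"] = pd.DataFrame(
            {
                el: enrichment_factor(conc[el], conc[ref_element], bg[el], bg[ref_element])
                for el in table.elements
            }
        )
    else:
        warnings.warn(
            f"reference element {ref_element!r} not in table; EF skipped"
        )
    return out


def synergistic_indices(cf: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PLI and NPI from the site-by-element Cf matrix."""
    pli = cf.apply(lambda row: pollution_load_index(row.to_numpy()), axis=1)
    npi = cf.apply(lambda row: nemerow_pollution_index(row.to_numpy()), axis=1)
    return pd.DataFrame({"PLI": pli, "NPI": npi})


def classify_matrix(values: pd.DataFrame | pd.Series, scheme: ClassificationScheme):
    """Apply a scheme elementwise, preserving shape."""
    if isinstance(values, pd.Series):
        return values.map(scheme.classify)
    return values.apply(lambda col: col.map(scheme.classify))


def class_distribution_table(
    label_matrix: pd.DataFrame, scheme: ClassificationScheme
) -> pd.DataFrame:
    """Class x element table of site percentages (survey-style layout)."""
    return pd.DataFrame(
        {el: class_distribution(label_matrix[el], scheme) for el in label_matrix}
    )


def pollution_report(
    table: SampleTable,
    refset: ReferenceSet | None = None,
    ref_element: str = "Al",
    schemes: Mapping[str, ClassificationScheme] | None = None,
) -> dict:
    """All five indices with labels and class distributions for one table."""
    schemes = dict(schemes) if schemes is not None else default_schemes()
    mats = elementwise_indices(table, refset=refset, ref_element=ref_element)
    syn = synergistic_indices(mats["Cf"])
    labels = {name: classify_matrix(mat, schemes[name]) for name, mat in mats.items()}
    labels["PLI"] = classify_matrix(syn["PLI"], schemes["PLI"])
    labels["NPI"] = classify_matrix(syn["NPI"], schemes["NPI"])
    distributions = {
        name: class_distribution_table(labels[name], schemes[name]) for name in mats
    }
    distributions["PLI"] = class_distribution(labels["PLI"], schemes["PLI"]).to_frame("PLI")
    distributions["NPI"] = class_distribution(labels["NPI"], schemes["NPI"]).to_frame("NPI")
    mean_index = {name: mat.mean() for name, mat in mats.items()}
    mean_index["PLI"] = float(syn["PLI"].mean())
    mean_index["NPI"] = float(syn["NPI"].mean())
    return {
        "elementwise": mats,
        "synergistic": syn,
        "labels": labels,
        "distributions": distributions,
        "mean_index": mean_index,
    }


def long_format(mats: Mapping[str, pd.DataFrame], labels: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """(site_id, element, index, value, class) long-format export."""
    frames = []
    for name, mat in mats.items():
        stacked = mat.stack()
        lab = labels[name].stack()
        frames.append(
            pd.DataFrame(
                {
                    "site_id": [i for i, _ in stacked.index],
                    "element": [e for _, e in stacked.index],
                    "index": name,
                    "value": stacked.to_numpy(),
                    "class": lab.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
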
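"""Constant tables and the sample-table container.

Everything downstream (pollution indices, ecological risk, health risk,
APCS-MLR) consumes a :class:`SampleTable` — a validated site-by-element
concentration matrix in mg/kg dry soil — together with a
:class:`ReferenceSet` of geochemical backgrounds (upper continental crust,
UCC), soil guideline values (WSA/ESA/MAC/CSQG) and Hakanson toxicity
response coefficients. The packaged constants live in
``data/reference.json``; users may override them with a file of the same
schema.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical element order used in every output table.
CANONICAL_ELEMENTS: tuple[str, ...] = (
    "Al", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn",
)


def _normalize_symbol(sym: str) -> str:
    """Case-normalize an element symbol ('CD' / 'cd' -> 'Cd')."""
    s = str(sym).strip()
    return s[:1].upper() + s[1:].lower() if s else s


class SampleTable:
    """Site-by-element concentration matrix (mg/kg dry soil).

    Parameters
    ----------
    data
        DataFrame with one row per sampling site (index = site id) and one
        column per element symbol. All concentrations must be finite and
        strictly positive; indices of every pollution index are undefined
        at zero, so non-positive cells are rejected rather than imputed.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.columns = [_normalize_symbol(c) for c in data.columns]
        data.index = data.index.astype(str)
        data.index.name = "site_id"
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site_ids: {dups}")
        if len(data.columns) != len(set(data.columns)):
            raise ValueError("duplicate element columns")
        for el in data.columns:
            col = pd.to_numeric(data[el], errors="coerce")
            bad = col.index[~np.isfinite(col) | (col <= 0)]
            if len(bad):
                raise ValueError(
                    f"invalid concentration: site {bad[0]!r}, element {el!r} "
                    "(must be finite and > 0)"
                )
            data[el] = col.astype(float)
        # canonicalize column order: known elements first, in survey order
        order = [e for e in CANONICAL_ELEMENTS if e in data.columns]
        order += [e for e in data.columns if e not in CANONICAL_ELEMENTS]
        self.data: pd.DataFrame = data[order]

    # -- basic accessors ---------------------------------------------------
    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def column(self, element: str) -> pd.Series:
        return self.data[_normalize_symbol(element)]

    def restrict(self, elements: Sequence[str]) -> "SampleTable":
        elements = [_normalize_symbol(e) for e in elements]
        missing = [e for e in elements if e not in self.data.columns]
        if missing:
            raise ValueError(f"element missing: {missing}")
        return SampleTable(self.data[elements])

    def require_multivariate(self) -> None:
        if self.n_sites < 2 or len(self.elements) < 2:
            raise ValueError(
                "multivariate operations need >= 2 sites and >= 2 elements"
            )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, elements: Sequence[str] | None = None) -> "SampleTable":
        df = pd.read_csv(path, index_col=0)
        table = cls(df)
        if elements is not None:
            table = table.restrict(elements)
        return table

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "site_id"
        out.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleTable({self.n_sites} sites x {len(self.elements)} elements)"


def read_sample_table(path, elements: Sequence[str] | None = None) -> SampleTable:
    """Read a site-by-element CSV (first column site_id, header = symbols)."""
    return SampleTable.from_csv(path, elements=elements)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-element background, guideline and toxicity-response constants.

    ``background`` is the geochemical background used by Cf/Igeo/EF — the
    packaged default is upper continental crust (UCC). ``tr`` carries the
    Hakanson toxicity response coefficients, defined only for Zn, Cu, Cd,
    Ni, Cr and Pb.
    """

    background: Mapping[str, float]
    guidelines: Mapping[str, Mapping[str, float]]
    tr: Mapping[str, float]
    version: int = 1

    def __post_init__(self):
        for el, v in self.background.items():
            if not (v > 0):
                raise ValueError(f"background must be > 0 (element {el})")

    def guideline(self, name: str) -> Mapping[str, float]:
        try:
            return self.guidelines[name]
        except KeyError:
            raise KeyError(
                f"unknown guideline {name!r}; available: {sorted(self.guidelines)}"
            ) from None


def _load_packaged_json(name: str) -> dict:
    with resources.files("soiltrace.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def default_reference_set(path=None) -> ReferenceSet:
    """Load the packaged reference constants (or a user override file)."""
    if path is None:
        raw = _load_packaged_json("reference.json")
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return ReferenceSet(
        background=dict(raw["background_ucc"]),
        guidelines={k: dict(v) for k, v in raw["guidelines"].items()},
        tr=dict(raw["toxicity_response"]),
        version=raw.get("version", 1),
    )


def load_survey_summary() -> tuple[pd.DataFrame, int]:
    """Published summary statistics of the 129-orchard Izmir survey.

    Returns a (statistics, n) pair: a DataFrame indexed by element with
    columns mean/median/sd/se/cv_percent/skewness/min/max, and the sample
    count. These printed statistics calibrate the synthetic generator and
    drive the worked examples; the raw per-site table was never deposited.
    """
    raw = _load_packaged_json("survey_summary.json")
    stats = pd.DataFrame.from_dict(raw["statistics"], orient="index")
    stats = stats.loc[raw["elements"]]
    return stats, int(raw["n"])


def flag_guideline_exceedance(
    summary: Mapping[str, float] | pd.Series,
    guideline: str,
    refset: ReferenceSet | None = None,
) -> pd.Series:
    """Flag elements whose statistic exceeds a named guideline value.

    Returns a Series indexed by element with values True / False, or the
    string ``"not assessed"`` where the guideline defines no value for that
    element (e.g. Al and Fe under MAC).
    """
    refset = refset if refset is not None else default_reference_set()
    limits = refset.guideline(guideline)
    summary = pd.Series(dict(summary))
    out = {}
    for el, value in summary.items():
        el = _normalize_symbol(el)
        if el in limits:
            out[el] = bool(value > limits[el])
        else:
            out[el] = "not assessed"
    return pd.Series(out, name=guideline)


# ---------------------------------------------------------------------------
# Classification schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered breakpoints and class labels for one index.

    ``lower_closed[i]`` says whether a value exactly equal to
    ``breakpoints[i]`` belongs to the class below the breakpoint. The
    printed schemes close some boundaries downward (Igeo <= 0 unpolluted,
    NPI <= 0.7 unpolluted) and some upward (2 <= EF < 5); boundaries the
    schemes leave open (e.g. Cf = 1) are resolved left-closed upward,
    [1, 3) -> moderate.
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    lower_closed: tuple[bool, ...]

    def __post_init__(self):
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need len(labels) == len(breakpoints) + 1")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if len(self.lower_closed) != len(self.breakpoints):
            raise ValueError("need one lower_closed flag per breakpoint")

    def classify(self, value: float) -> str:
        """Label of the interval containing ``value`` (total over finite x)."""
        if not np.isfinite(value):
            raise ValueError(f"cannot classify non-finite value {value!r}")
        for i, bp in enumerate(self.breakpoints):
            if value < bp or (value == bp and self.lower_closed[i]):
                return self.labels[i]
        return self.labels[-1]


def default_schemes() -> dict[str, ClassificationScheme]:
    """The eight packaged classification schemes (one per index)."""
    return {
        "Igeo": ClassificationScheme(
            "Igeo",
            (0, 1, 2, 3, 4, 5),
            (
                "Unpolluted",
                "Unpolluted to moderately polluted",
                "Moderately polluted",
                "Moderately to heavily polluted",
                "Heavily polluted",
                "Heavily to extremely polluted",
                "Extremely polluted",
            ),
            (True, False, False, False, False, False),
        ),
        "Cf": ClassificationScheme(
            "Cf",
            (1, 3, 6),
            (
                "Low contamination",
                "Moderate contamination",
                "Considerable contamination",
                "Very high contamination",
            ),
            (False, False, False),
        ),
        "EF": ClassificationScheme(
            "EF",
            (2, 5, 20, 40),
            (
                "Minimal enrichment",
                "Moderate enrichment",
                "Significant enrichment",
                "Very high enrichment",
                "Extremely high enrichment",
            ),
            (False, False, False, False),
        ),
        "PLI": ClassificationScheme(
            "PLI",
            (1,),
            ("Baseline contamination", "High contamination"),
            (True,),
        ),
        "NPI": ClassificationScheme(
            "NPI",
            (0.7, 1, 2, 3),
            (
                "Unpolluted",
                "Warning line of pollution",
                "Low polluted",
                "Moderately polluted",
                "Strongly polluted",
            ),
            (True, True, True, True),
        ),
        "Er": ClassificationScheme(
            "Er",
            (40, 80, 160, 320),
            (
                "Low potential ecological risk",
                "Moderate potential ecological risk",
                "Considerable potential ecological risk",
                "High potential ecological risk",
                "Very high potential ecological risk",
            ),
            (False, False, False, False),
        ),
        "RI": ClassificationScheme(
            "RI",
            (150, 300, 600),
            (
                "Low ecological risk",
                "Moderate ecological risk",
                "Considerable ecological risk",
                "Very high ecological risk",
            ),
            (False, False, False),
        ),
        "NRI": ClassificationScheme(
            "NRI",
            (40, 80, 160, 320),
            (
                "Low risk",
                "Moderate risk",
                "Considerable risk",
                "High risk",
                "Very high risk",
            ),
            (True, True, True, True),
        ),
    }
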
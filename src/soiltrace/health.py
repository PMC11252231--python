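"""USEPA residential health risk: hazard quotients and carcinogenic risk.

Three exposure routes (incidental soil ingestion, dermal contact,
inhalation of resuspended particulates) are evaluated for child and adult
residents. Non-carcinogenic hazard quotients divide the chronic daily
intake by the oral reference dose (RfDo, dermal additionally by GIABS) or,
for inhalation, relate the air concentration implied by the particulate
emission factor (PEF) to the reference concentration (RfC). Carcinogenic
risk uses age-adjusted lifetime ingestion/dermal factors (IFS, DFS — child
plus adult terms) with the oral slope factor, and lifetime inhalation with
the inhalation unit risk (IUR); it is computed only for the elements that
carry a slope factor or unit risk (Cr, Cd, Ni, Co in the packaged table).

Units follow the RSL convention: soil concentration mg/kg, so the 1e6
divisor converts mg/kg to kg/kg intake; the 1000 factor in inhalation CR
converts IUR per-ug/m3 to per-mg/m3. Averaging time is in days; for
non-carcinogens AT = ED x 365, for carcinogens AT = 70 y x 365.

The exposure-frequency symbol is written ``efr`` (days/year) throughout to
avoid collision with the enrichment factor EF.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

ROUTES = ("ingestion", "dermal", "inhalation")
RECEPTORS = ("child", "adult")


@dataclass(frozen=True)
class ReceptorBlock:
    """Age-specific exposure parameters for one receptor."""

    irs: float   # soil ingestion rate, mg/day
    ed: float    # exposure duration, years
    bw: float    # body weight, kg
    sa: float    # exposed skin surface, cm2/day
    af: float    # soil-to-skin adherence, mg/cm2

    def __post_init__(self):
        for name in ("irs", "ed", "bw", "sa"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.af < 0:
            raise ValueError("af must be >= 0")


@dataclass(frozen=True)
class ExposureScenario:
    """Residential exposure scenario with child and adult sub-blocks.

    Defaults are the USEPA RSL residential values; every field is
    overridable (e.g. via a YAML/JSON config in the pipeline).
    """

    efr: float = 350.0            # exposure frequency, days/year
    pef: float = 1.36e9           # particulate emission factor, m3/kg
    at_carcinogenic_years: float = 70.0
    child: ReceptorBlock = field(
        default_factory=lambda: ReceptorBlock(irs=200, ed=6, bw=15, sa=2373, af=0.2)
    )
    adult: ReceptorBlock = field(
        default_factory=lambda: ReceptorBlock(irs=100, ed=20, bw=80, sa=6032, af=0.07)
    )

    def block(self, receptor: str) -> ReceptorBlock:
        if receptor not in RECEPTORS:
            raise ValueError(f"receptor must be one of {RECEPTORS}")
        return getattr(self, receptor)

    def at_noncarcinogenic(self, receptor: str) -> float:
        """Averaging time in days for the non-carcinogenic endpoint."""
        return self.block(receptor).ed * 365.0

    @property
    def at_carcinogenic(self) -> float:
        return self.at_carcinogenic_years * 365.0

    @property
    def ed_lifetime(self) -> float:
        """Exposure duration for lifetime inhalation risk (child + adult)."""
        return self.child.ed + self.adult.ed


@dataclass(frozen=True)
class ToxicityEntry:
    rfdo: float | None = None    # oral reference dose, mg/kg-day
    rfc: float | None = None     # inhalation reference concentration, mg/m3
    absd: float = 0.001          # dermal absorption fraction
    giabs: float = 1.0           # gastrointestinal absorption fraction
    rba: float = 1.0             # relative bioavailability
    csfo: float | None = None    # oral slope factor, (mg/kg-day)^-1
    iur: float | None = None     # inhalation unit risk, (ug/m3)^-1

    def __post_init__(self):
        for name in ("absd", "giabs", "rba"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def default_toxicity_table(path=None) -> dict[str, ToxicityEntry]:
    """Packaged RSL-convention toxicity values (or a user override file)."""
    if path is None:
        with resources.files("soiltrace.data").joinpath("toxicity.json").open() as fh:
            raw = json.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out = {}
    for el, entry in raw["elements"].items():
        out[el] = ToxicityEntry(
            rfdo=entry.get("RfDo"),
            rfc=entry.get("RfC"),
            absd=entry.get("ABSd", 0.001),
            giabs=entry.get("GIABS", 1.0),
            rba=entry.get("RBA", 1.0),
            csfo=entry.get("CSFo"),
            iur=entry.get("IUR"),
        )
    return out


# ---------------------------------------------------------------------------
# Route-level quotients
# ---------------------------------------------------------------------------

def hq_route(
    cs: float,
    route: str,
    receptor: str,
    scenario: ExposureScenario,
    tox: ToxicityEntry,
) -> float:
    """Non-carcinogenic hazard quotient for one element, route, receptor."""
    b = scenario.block(receptor)
    at = scenario.at_noncarcinogenic(receptor)
    if route == "ingestion":
        if tox.rfdo is None:
            raise ValueError("missing RfDo for ingestion")
        return (cs * b.irs * tox.rba * scenario.efr * b.ed) / (
            b.bw * at * tox.rfdo * 1e6
        )
    if route == "dermal":
        if tox.rfdo is None:
            raise ValueError("missing RfDo for dermal")
        return (cs * b.sa * b.af * tox.absd * scenario.efr * b.ed) / (
            b.bw * at * tox.rfdo * tox.giabs * 1e6
        )
    if route == "inhalation":
        if tox.rfc is None:
            raise ValueError("missing RfC for inhalation")
        return (cs * scenario.efr * b.ed) / (at * tox.rfc * scenario.pef)
    raise ValueError(f"unknown route {route!r}")


def ifs(scenario: ExposureScenario) -> float:
    """Age-adjusted soil ingestion factor, mg (child term + adult term)."""
    c, a = scenario.child, scenario.adult
    return (
        scenario.efr * a.ed * a.irs / a.bw
        + scenario.efr * c.ed * c.irs / c.bw
    )


def dfs(scenario: ExposureScenario) -> float:
    """Age-adjusted dermal contact factor, mg (SA*AF in place of IRS)."""
    c, a = scenario.child, scenario.adult
    return (
        scenario.efr * a.ed * a.sa * a.af / a.bw
        + scenario.efr * c.ed * c.sa * c.af / c.bw
    )


def cr_route(
    cs: float,
    route: str,
    scenario: ExposureScenario,
    tox: ToxicityEntry,
) -> float:
    """Lifetime carcinogenic risk for one element and route.

    Ingestion and dermal use the age-adjusted IFS/DFS factors; inhalation
    uses the lifetime exposure duration (child + adult years).
    """
    at = scenario.at_carcinogenic
    if route == "ingestion":
        if tox.csfo is None:
            raise ValueError("missing CSFo for ingestion")
        return (cs * ifs(scenario) * tox.rba * tox.csfo) / (at * 1e6)
    if route == "dermal":
        if tox.csfo is None:
            raise ValueError("missing CSFo for dermal")
        return (cs * dfs(scenario) * tox.absd * tox.csfo) / (at * tox.giabs * 1e6)
    if route == "inhalation":
        if tox.iur is None:
            raise ValueError("missing IUR for inhalation")
        return (cs * scenario.efr * scenario.ed_lifetime * tox.iur * 1000.0) / (
            at * scenario.pef
        )
    raise ValueError(f"unknown route {route!r}")


# ---------------------------------------------------------------------------
# Aggregation (CHQ, HI, THI; CCR, TCR, CTCR)
# ---------------------------------------------------------------------------

@dataclass
class RiskResult:
    """All hazard and risk aggregates for one set of soil concentrations.

    hq[receptor]: element x route DataFrame (NaN where a route was skipped
    for lack of a toxicity value). hi[receptor]: per-element sum over
    routes. chq[receptor]: per-route sum over elements. thi[receptor]:
    grand total — identical whether elements or routes are summed first.
    cr/tcr/ccr/ctcr are the carcinogenic analogues (receptor-free: lifetime
    age-adjusted).
    """

    hq: dict[str, pd.DataFrame]
    hi: dict[str, pd.Series]
    chq: dict[str, pd.Series]
    thi: dict[str, float]
    cr: pd.DataFrame
    tcr: pd.Series
    ccr: pd.Series
    ctcr: float


def aggregate_risks(
    concentrations: Mapping[str, float] | pd.Series,
    scenario: ExposureScenario | None = None,
    toxicity: Mapping[str, ToxicityEntry] | None = None,
) -> RiskResult:
    """Compute HQ/HI/CHQ/THI and CR/TCR/CCR/CTCR for mean soil levels.

    Elements or routes without the required toxicity value are skipped
    with a warning (left as NaN), never treated as zero risk.
    """
    scenario = scenario if scenario is not None else ExposureScenario()
    toxicity = toxicity if toxicity is not None else default_toxicity_table()
    conc = pd.Series(dict(concentrations)).astype(float)

    hq: dict[str, pd.DataFrame] = {}
    for receptor in RECEPTORS:
        mat = pd.DataFrame(index=conc.index, columns=list(ROUTES), dtype=float)
        for el, cs in conc.items():
            if el not in toxicity:
                warnings.warn(f"no toxicity entry for {el}; skipped")
                continue
            for route in ROUTES:
                try:
                    mat.loc[el, route] = hq_route(cs, route, receptor, scenario, toxicity[el])
                except ValueError as exc:
                    warnings.warn(f"HQ {el}/{route} skipped: {exc}")
        hq[receptor] = mat

    hi = {r: hq[r].sum(axis=1, skipna=True) for r in RECEPTORS}
    chq = {r: hq[r].sum(axis=0, skipna=True) for r in RECEPTORS}
    thi = {r: float(hi[r].sum()) for r in RECEPTORS}

    carcinogens = [el for el in conc.index
                   if el in toxicity
                   and (toxicity[el].csfo is not None or toxicity[el].iur is not None)]
    cr = pd.DataFrame(index=carcinogens, columns=list(ROUTES), dtype=float)
    for el in carcinogens:
        for route in ROUTES:
            try:
                cr.loc[el, route] = cr_route(conc[el], route, scenario, toxicity[el])
            except ValueError as exc:
                warnings.warn(f"CR {el}/{route} skipped: {exc}")
    tcr = cr.sum(axis=1, skipna=True)
    ccr = cr.sum(axis=0, skipna=True)
    return RiskResult(
        hq=hq, hi=hi, chq=chq, thi=thi,
        cr=cr, tcr=tcr, ccr=ccr, ctcr=float(tcr.sum()),
    )


def total_carcinogenic_risk(cr_by_route: Mapping[str, float] | pd.Series) -> float:
    """TCR (or CTCR): sum of carcinogenic risk over exposure routes."""
    cr = pd.Series(dict(cr_by_route)).astype(float)
    unknown = set(cr.index) - set(ROUTES)
    if unknown:
        raise ValueError(f"unknown routes {sorted(unknown)}")
    return float(cr.sum())


def route_shares(cr_by_route: Mapping[str, float] | pd.Series) -> pd.Series:
    """Percent contribution of each route to the summed risk."""
    cr = pd.Series(dict(cr_by_route)).astype(float)
    total = cr.sum()
    if not (total > 0):
        raise ValueError("total risk must be > 0")
    return 100.0 * cr / total


def risk_tables(result: RiskResult) -> dict[str, pd.DataFrame]:
    """Flat CSV-ready tables (element x route x receptor; carcinogenic)."""
    rows = []
    for receptor in RECEPTORS:
        stacked = result.hq[receptor].stack(future_stack=True)
        for (el, route), v in stacked.items():
            rows.append({"element": el, "route": route, "receptor": receptor, "HQ": v})
    hq_long = pd.DataFrame(rows)
    carc = result.cr.copy()
    carc["TCR"] = result.tcr
    return {"hq_long": hq_long, "carcinogenic": carc}
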
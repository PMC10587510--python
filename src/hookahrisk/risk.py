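"""Exposure and risk indices: chronic daily intake, hazard quotient,
cancer risk, and the standard risk-band classification.

The intake model is the usual chronic-exposure average

    CDI = (CF × IR × EF × ED) / (BW × AT)        [mg kg⁻¹ day⁻¹]

with CF the exposure-point concentration (mg/kg), IR the intake rate of
the material (kg/day), EF the exposure frequency (days/year), ED the
exposure duration (years), BW body weight (kg) and AT the averaging time
in days. Noncancer risk is the hazard quotient HQ = CDI / RfD (flagged
above 1); cancer risk is CR = CDI × CSF, banded as negligible
(CR ≤ 10⁻⁶), tolerable, or high (CR > 10⁻⁴).

Elements without a published RfD or slope factor yield a
``not_applicable`` entry — absence of a reference value is not absence of
risk, so it is never reported as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .core_data import ConcentrationTable, ValidationError, substitute_censored

__all__ = [
    "ExposureScenario",
    "chronic_daily_intake",
    "hazard_quotient",
    "cancer_risk",
    "classify_cr",
    "risk_table",
    "hazard_index",
    "CR_NEGLIGIBLE",
    "CR_HIGH",
]

#: Lifetime cancer-probability band edges: ≤ one-in-a-million is negligible,
#: > one-in-ten-thousand is high.
CR_NEGLIGIBLE = 1e-6
CR_HIGH = 1e-4

BANDS = ("negligible", "tolerable", "high", "not_applicable")


@dataclass(frozen=True)
class ExposureScenario:
    """Chronic-exposure assumptions.

    IR: intake rate of the smoked material, kg/day
    EF: exposure frequency, days/year (≤ 365)
    ED: exposure duration, years
    BW: body weight, kg
    AT: averaging time, days (70-year lifetime = 25 550 for cancer endpoints)
    """

    IR: float
    EF: float
    ED: float
    BW: float
    AT: float

    def __post_init__(self) -> None:
        for name in ("IR", "EF", "ED", "BW", "AT"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"scenario field {name} must be > 0")
        if self.EF > 365:
            raise ValidationError("EF cannot exceed 365 days/year")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExposureScenario":
        """Load keys ``IR_kg_per_day, EF_days_per_year, ED_years, BW_kg,
        AT_days``."""
        cfg = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                IR=float(cfg["IR_kg_per_day"]),
                EF=float(cfg["EF_days_per_year"]),
                ED=float(cfg["ED_years"]),
                BW=float(cfg["BW_kg"]),
                AT=float(cfg["AT_days"]),
            )
        except KeyError as exc:
            raise ValidationError(f"scenario file lacks key {exc}") from None


def chronic_daily_intake(cf: float, scenario: ExposureScenario) -> float:
    """CDI = (CF × IR × EF × ED) / (BW × AT); linear in CF."""
    if cf < 0 or not math.isfinite(cf):
        raise ValidationError("CF must be a finite non-negative concentration")
    return cf * scenario.IR * scenario.EF * scenario.ED / (scenario.BW * scenario.AT)


def hazard_quotient(cdi: float, rfd: float | None) -> tuple[float | None, bool]:
    """HQ = CDI / RfD, with the hazard flag set when HQ > 1.

    An absent RfD (None/NaN) gives ``(None, False)`` — not applicable —
    rather than an exception; a non-positive RfD is an input error.
    """
    if rfd is None or (isinstance(rfd, float) and math.isnan(rfd)):
        return None, False
    if rfd <= 0:
        raise ValidationError("RfD must be strictly positive")
    hq = cdi / rfd
    return hq, hq > 1.0


def cancer_risk(cdi: float, slope_factor: float | None) -> tuple[float | None, str]:
    """CR = CDI × CSF, with its band; absent CSF → (None, not_applicable)."""
    if slope_factor is None or (isinstance(slope_factor, float) and math.isnan(slope_factor)):
        return None, "not_applicable"
    if slope_factor < 0:
        raise ValidationError("slope factor must be non-negative")
    cr = cdi * slope_factor
    return cr, classify_cr(cr)


def classify_cr(cr: float) -> str:
    """Risk band: CR ≤ 1e−6 negligible (boundary inclusive), CR > 1e−4
    high, tolerable in between."""
    if cr < 0 or not math.isfinite(cr):
        raise ValidationError("CR must be a finite non-negative probability")
    if cr <= CR_NEGLIGIBLE:
        return "negligible"
    if cr > CR_HIGH:
        return "high"
    return "tolerable"


def risk_table(
    table: ConcentrationTable,
    toxrefs: pd.DataFrame,
    scenario: ExposureScenario,
    source: str = "raw",
    balance: pd.DataFrame | None = None,
    policy: str = "zero",
) -> pd.DataFrame:
    """Per-(sample, element) risk matrix.

    ``source='raw'`` takes CF directly from the raw-tobacco concentration;
    ``source='smoke'`` scales it by the smoke retention fraction from a
    mass-balance ``partition_table`` result (``balance``), CF = c_raw ×
    smoke%/100. Rows with a missing CF are dropped. Columns: ``CF, CDI,
    HQ, hazard_flag, CR, band``; HQ/CR are NaN where the element lacks the
    corresponding reference value (band ``not_applicable`` when it lacks a
    slope factor).
    """
    if source not in ("raw", "smoke"):
        raise ValidationError(f"CF source must be 'raw' or 'smoke', got {source!r}")
    df = substitute_censored(table, policy)
    raw = df[df["compartment"] == "raw"].dropna(subset=["value"])
    if raw.empty:
        raise ValidationError("no raw-compartment records to assess")
    cf = raw.set_index(["sample_id", "element"])["value"]
    if source == "smoke":
        if balance is None:
            raise ValidationError("source='smoke' needs a mass-balance table")
        frac = balance.set_index(["sample_id", "element"])["smoke_percent"] / 100.0
        cf = (cf * frac).dropna()

    rows = []
    for (sample, element), value in cf.items():
        cdi = chronic_daily_intake(value, scenario)
        rfd = toxrefs["rfd_mg_kg_day"].get(element)
        sf = toxrefs["slope_factor"].get(element)
        hq, flagged = hazard_quotient(cdi, rfd)
        cr, band = cancer_risk(cdi, sf)
        rows.append((sample, element, value, cdi, hq, flagged, cr, band))
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "element", "CF", "CDI", "HQ", "hazard_flag", "CR", "band"],
    )
    return out


def hazard_index(risk: pd.DataFrame) -> pd.Series:
    """Per-sample hazard index: sum of the defined HQs."""
    return risk.groupby("sample_id")["HQ"].sum(min_count=1).rename("hazard_index")
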
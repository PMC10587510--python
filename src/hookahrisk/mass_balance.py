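"""Partition each element's per-session burden across ash, bowl water and
smoke.

A smoking session burns a known charge of tobacco; afterwards part of each
element's mass sits in the ash residue, part has dissolved into the bowl
water, and the remainder is attributed to the inhaled smoke by difference:

    smoke% = 100 × (m_raw − m_ash − m_water) / m_raw

with burdens in mg per session:

    m_raw   = c_raw  [mg/kg] × tobacco_mass [kg]
    m_ash   = c_ash  [mg/kg] × ash_yield × tobacco_mass [kg]
    m_water = c_water [mg/L] × water_volume [L]

The three scale factors (ash yield, bowl-water volume, tobacco charge) are
physical session parameters that concentration tables alone do not pin
down, so they are required inputs with no silent defaults. Measurement
noise can push the difference outside [0, 100]; such values are clipped
and flagged, never silently propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .core_data import ConcentrationTable, ValidationError, substitute_censored

__all__ = [
    "PartitionParameters",
    "compartment_burdens",
    "smoke_retention_percent",
    "partition_table",
    "smoke_percent_range",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionParameters:
    """Session-scale physical parameters of the mass balance.

    ash_yield: mass fraction of the tobacco charge remaining as ash, in (0, 1)
    water_volume: bowl water per session, L
    tobacco_mass: tobacco charge burned per session, kg
    """

    ash_yield: float
    water_volume: float
    tobacco_mass: float

    def __post_init__(self) -> None:
        if not 0 < self.ash_yield < 1:
            raise ValidationError(f"ash_yield must be in (0,1), got {self.ash_yield}")
        if self.water_volume <= 0:
            raise ValidationError("water_volume must be > 0 L")
        if self.tobacco_mass <= 0:
            raise ValidationError("tobacco_mass must be > 0 kg")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PartitionParameters":
        """Load keys ``ash_yield``, ``water_volume_l``, ``tobacco_mass_kg``."""
        cfg = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                ash_yield=float(cfg["ash_yield"]),
                water_volume=float(cfg["water_volume_l"]),
                tobacco_mass=float(cfg["tobacco_mass_kg"]),
            )
        except KeyError as exc:
            raise ValidationError(f"partition parameter file lacks key {exc}") from None


def compartment_burdens(
    raw_c: float, ash_c: float, water_c: float, params: PartitionParameters
) -> tuple[float, float, float]:
    """Per-session element burdens (mg) in raw tobacco, ash, and bowl water,
    from concentrations in mg/kg (solids) and mg/L (water)."""
    if min(raw_c, ash_c, water_c) < 0:
        raise ValidationError("concentrations must be non-negative")
    burden_raw = raw_c * params.tobacco_mass
    burden_ash = ash_c * params.ash_yield * params.tobacco_mass
    burden_water = water_c * params.water_volume
    return burden_raw, burden_ash, burden_water


def smoke_retention_percent(
    burden_raw: float, burden_ash: float, burden_water: float
) -> tuple[float, bool]:
    """Percent of the raw burden attributed to smoke, by difference.

    Returns ``(percent, clipped)``; the percent is clipped into [0, 100]
    with the flag set when the raw difference fell outside it.
    """
    if burden_raw <= 0:
        raise ValidationError("smoke retention undefined for zero raw burden")
    pct = 100.0 * (burden_raw - burden_ash - burden_water) / burden_raw
    clipped = pct < 0 or pct > 100
    return min(max(pct, 0.0), 100.0), clipped


def partition_table(
    table: ConcentrationTable,
    params: PartitionParameters,
    policy: str = "zero",
) -> pd.DataFrame:
    """Full per-(sample, element) partition of the study table.

    Requires raw, ash and water records for every sample. Rows whose raw
    burden is zero or missing after censoring substitution are skipped
    (logged), since the smoke share is then undefined. Columns:
    ``burden_raw/ash/water`` (mg per session), ``smoke_percent``,
    ``clipped``.
    """
    df = substitute_censored(table, policy)
    have = df.groupby("sample_id")["compartment"].agg(set)
    lacking = {s for s, comps in have.items() if comps != {"raw", "ash", "water"}}
    if lacking:
        raise ValidationError(
            f"samples missing a compartment: {sorted(lacking)} "
            "(raw, ash and water are all required)"
        )
    wide = df.pivot_table(
        index=["sample_id", "element"],
        columns="compartment",
        values="value",
        dropna=False,
    )
    rows = []
    for (sample, element), r in wide.iterrows():
        raw_c = r.get("raw")
        ash_c = r.get("ash")
        water_c = r.get("water")
        if pd.isna(raw_c) or raw_c <= 0:
            logger.info(
                "skipping %s/%s: raw concentration %s under policy=%s",
                sample, element, "missing" if pd.isna(raw_c) else "zero", policy,
            )
            continue
        # a missing ash/water cell contributes nothing to the balance
        ash_c = 0.0 if pd.isna(ash_c) else ash_c
        water_c = 0.0 if pd.isna(water_c) else water_c
        b_raw, b_ash, b_water = compartment_burdens(raw_c, ash_c, water_c, params)
        pct, clipped = smoke_retention_percent(b_raw, b_ash, b_water)
        rows.append((sample, element, b_raw, b_ash, b_water, pct, clipped))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "element",
            "burden_raw", "burden_ash", "burden_water",
            "smoke_percent", "clipped",
        ],
    )


def smoke_percent_range(partition: pd.DataFrame) -> pd.DataFrame:
    """Per-sample min/max of element-wise smoke percentages."""
    g = partition.groupby("sample_id")["smoke_percent"]
    return g.agg(["min", "max"]).rename(
        columns={"min": "smoke_percent_min", "max": "smoke_percent_max"}
    ).reset_index()


def partition_to_wide_csv(partition: pd.DataFrame, path: str | Path) -> None:
    """Write the element × sample smoke-percent matrix; clipped cells are
    suffixed ``*``."""
    txt = partition.copy()
    txt["cell"] = [
        f"{p:.1f}*" if c else f"{p:.1f}"
        for p, c in zip(txt["smoke_percent"], txt["clipped"])
    ]
    wide = txt.pivot(index="element", columns="sample_id", values="cell")
    wide.to_csv(path)
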
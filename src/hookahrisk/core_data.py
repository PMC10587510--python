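"""Censored multi-element concentration tables.

ICP-MS panels report each element either as a measured concentration, as
``<LOD`` when the signal fell below the detection limit (left-censored),
or not at all. This module holds the data model for such tables across the
three physical compartments of a hookah session — raw tobacco, combustion
ash, and bowl water — plus parsing, unit normalization, censoring
substitution, and the bundled study fixtures.

Units follow the field convention: ppm/ppb are mass-per-mass for solids
(mg/kg, µg/kg) and mass-per-volume for water (mg/L, µg/L). After
:func:`normalize_units` every solid record is mg/kg and every water record
is mg/L.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "MAIN_ELEMENTS",
    "COMPARTMENTS",
    "CensoredValue",
    "ConcentrationTable",
    "parse_censored",
    "format_censored",
    "normalize_units",
    "substitute_censored",
    "load_concentration_table",
    "load_toxicity_references",
    "load_sample_meta",
    "load_study_tables",
    "load_study_meta",
    "load_toxicity_fixture",
    "load_lod_fixture",
    "ValidationError",
]

#: The 29-element ICP-MS panel of the study, in periodic-symbol form.
ELEMENTS: tuple[str, ...] = (
    "Al", "As", "B", "Ba", "Ca", "Cd", "Ce", "Co", "Cr", "Cu",
    "Fe", "Hg", "K", "Mg", "Mn", "Mo", "Na", "Ni", "P", "Pb",
    "S", "Sb", "Se", "Si", "Sn", "Sr", "Ti", "V", "Zn",
)

#: The five macro-elements whose joint share of the total is reported.
MAIN_ELEMENTS: tuple[str, ...] = ("Ca", "K", "Na", "Mg", "P")

COMPARTMENTS: tuple[str, ...] = ("raw", "ash", "water")
SOLID_COMPARTMENTS = frozenset({"raw", "ash"})

MISSING_TOKENS = frozenset({"*****", "", "na", "nan", "nd"})

# canonical unit -> (scale to mg-based unit, is mass-per-volume)
_UNIT_ALIASES = {
    "mg/kg": ("mg/kg", 1.0, False),
    "ppm_solid": ("mg/kg", 1.0, False),
    "ug/kg": ("ug/kg", 1e-3, False),
    "µg/kg": ("ug/kg", 1e-3, False),
    "ppb_solid": ("ug/kg", 1e-3, False),
    "mg/l": ("mg/L", 1.0, True),
    "ppm_water": ("mg/L", 1.0, True),
    "ug/l": ("ug/L", 1e-3, True),
    "µg/l": ("ug/L", 1e-3, True),
    "ppb_water": ("ug/L", 1e-3, True),
}

CENSOR_POLICIES = ("zero", "half_lod", "lod")


class ValidationError(ValueError):
    """A concentration or toxicity table violates its schema."""


def _canon_unit(unit: str, compartment: str) -> tuple[str, float, bool]:
    key = str(unit).strip().lower()
    if key in ("ppm", "ppb"):
        key = f"{key}_{'water' if compartment == 'water' else 'solid'}"
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown unit {unit!r}") from None


@dataclass(frozen=True)
class CensoredValue:
    """A single concentration cell.

    ``state`` is one of ``observed`` (``value`` is the measurement),
    ``censored`` (``value`` is the detection limit the cell fell below),
    or ``missing`` (``value`` is ``None``).
    """

    state: Literal["observed", "censored", "missing"]
    value: float | None = None

    def __post_init__(self) -> None:
        if self.state not in ("observed", "censored", "missing"):
            raise ValidationError(f"bad censoring state {self.state!r}")
        if self.state == "missing":
            if self.value is not None:
                raise ValidationError("missing value must carry no number")
        else:
            if self.value is None or not np.isfinite(self.value) or self.value < 0:
                raise ValidationError(
                    f"{self.state} value must be a finite non-negative number, "
                    f"got {self.value!r}"
                )

    @classmethod
    def observed(cls, value: float) -> "CensoredValue":
        return cls("observed", float(value))

    @classmethod
    def censored(cls, lod: float) -> "CensoredValue":
        return cls("censored", float(lod))

    @classmethod
    def missing(cls) -> "CensoredValue":
        return cls("missing", None)

    def substitute(self, policy: str = "zero") -> float:
        """Numeric stand-in under a censoring policy; NaN when missing."""
        if policy not in CENSOR_POLICIES:
            raise ValidationError(f"unknown censoring policy {policy!r}")
        if self.state == "missing":
            return float("nan")
        if self.state == "observed":
            return float(self.value)
        return {"zero": 0.0, "half_lod": self.value / 2.0, "lod": float(self.value)}[policy]


def parse_censored(token: str) -> CensoredValue:
    """Parse one table cell: ``"<50"`` → censored at 50, ``"221"`` →
    observed 221, ``"*****"`` or an empty cell → missing."""
    text = str(token).strip()
    if text.lower() in MISSING_TOKENS:
        return CensoredValue.missing()
    if text.startswith("<"):
        body = text[1:].strip()
        try:
            lod = float(body.replace(",", ""))
        except ValueError:
            raise ValidationError(f"cannot parse censored cell {token!r}") from None
        return CensoredValue.censored(lod)
    try:
        return CensoredValue.observed(float(text.replace(",", "")))
    except ValueError:
        raise ValidationError(f"cannot parse concentration cell {token!r}") from None


def format_censored(cv: CensoredValue) -> str:
    """Inverse of :func:`parse_censored` (round-trips every state)."""
    if cv.state == "missing":
        return "*****"
    if cv.state == "censored":
        return f"<{cv.value:g}"
    return f"{cv.value:g}"


class ConcentrationTable:
    """Tidy samples × compartments × elements table of censored values.

    Backed by a DataFrame with columns ``sample_id``, ``compartment``,
    ``element``, ``state``, ``value``, ``unit`` — one row per cell, the
    (sample, compartment, element) triple unique. ``value`` is NaN for
    missing cells and holds the LOD for censored ones.
    """

    REQUIRED = ("sample_id", "compartment", "element", "state", "value", "unit")

    def __init__(self, df: pd.DataFrame):
        missing_cols = set(self.REQUIRED) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"missing columns: {sorted(missing_cols)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["value"] = pd.to_numeric(df["value"])
        if len(df) == 0:
            raise ValidationError("empty concentration table")

        bad_comp = set(df["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValidationError(f"unknown compartments: {sorted(bad_comp)}")
        bad_el = set(df["element"]) - set(ELEMENTS)
        if bad_el:
            raise ValidationError(
                f"unknown element symbols: {sorted(bad_el)} "
                f"(panel is the fixed 29-element set)"
            )
        bad_state = set(df["state"]) - {"observed", "censored", "missing"}
        if bad_state:
            raise ValidationError(f"unknown censoring states: {sorted(bad_state)}")

        dup = df.duplicated(["sample_id", "compartment", "element"])
        if dup.any():
            rows = df.loc[dup, ["sample_id", "compartment", "element"]]
            raise ValidationError(
                "duplicate (sample, compartment, element) records: "
                + "; ".join("/".join(r) for r in rows.itertuples(index=False))
            )

        present = df["state"] != "missing"
        if df.loc[present, "value"].isna().any() or (df.loc[present, "value"] < 0).any():
            raise ValidationError("observed/censored values must be finite and >= 0")
        if df.loc[~present, "value"].notna().any():
            raise ValidationError("missing cells must carry no value")

        for comp, unit in df[["compartment", "unit"]].drop_duplicates().itertuples(index=False):
            _, _, per_volume = _canon_unit(unit, comp)
            if per_volume != (comp == "water"):
                raise ValidationError(
                    f"unit {unit!r} is not valid for compartment {comp!r} "
                    "(solids take mass-per-mass, water mass-per-volume)"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        s = self.df["sample_id"].nunique()
        c = self.df["compartment"].nunique()
        e = self.df["element"].nunique()
        return f"ConcentrationTable({s} samples x {c} compartments x {e} elements)"

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def compartments(self) -> list[str]:
        return [c for c in COMPARTMENTS if c in set(self.df["compartment"])]

    def select(self, *, sample_id=None, compartment=None, elements=None) -> "ConcentrationTable":
        df = self.df
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        if compartment is not None:
            df = df[df["compartment"] == compartment]
        if elements is not None:
            df = df[df["element"].isin(list(elements))]
        if len(df) == 0:
            raise ValidationError("selection matched no records")
        return ConcentrationTable(df)

    def cell(self, sample_id: str, compartment: str, element: str) -> CensoredValue:
        m = self.df[
            (self.df["sample_id"] == sample_id)
            & (self.df["compartment"] == compartment)
            & (self.df["element"] == element)
        ]
        if len(m) != 1:
            raise KeyError((sample_id, compartment, element))
        row = m.iloc[0]
        if row["state"] == "missing":
            return CensoredValue.missing()
        return CensoredValue(row["state"], float(row["value"]))

    def normalize_units(self) -> "ConcentrationTable":
        return normalize_units(self)

    def substitute(self, policy: str = "zero") -> pd.DataFrame:
        return substitute_censored(self, policy)

    def concat(self, other: "ConcentrationTable") -> "ConcentrationTable":
        return ConcentrationTable(pd.concat([self.df, other.df], ignore_index=True))

    def to_long_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["value"] = [
            format_censored(
                CensoredValue(s, None if s == "missing" else v)
            )
            for s, v in zip(out["state"], out["value"])
        ]
        out.drop(columns="state").to_csv(path, index=False)


def normalize_units(table: ConcentrationTable) -> ConcentrationTable:
    """Convert every solid record to mg/kg and every water record to mg/L.

    µg-based values (and their LODs) are divided by 1000; censoring states
    are preserved and the operation is idempotent.
    """
    df = table.df.copy()
    scales = np.ones(len(df))
    units = []
    for i, (comp, unit) in enumerate(zip(df["compartment"], df["unit"])):
        _, scale, per_volume = _canon_unit(unit, comp)
        scales[i] = scale
        units.append("mg/L" if per_volume else "mg/kg")
    df["value"] = df["value"] * scales
    df["unit"] = units
    return ConcentrationTable(df)


def substitute_censored(table: ConcentrationTable, policy: str = "zero") -> pd.DataFrame:
    """Replace censored cells by 0, LOD/2 or LOD per ``policy``.

    Returns a plain tidy DataFrame (``sample_id, compartment, element,
    value, unit``); missing cells come through as NaN and observed ones
    unchanged. The table must be normalized first so LODs are on the
    mg scale.
    """
    if policy not in CENSOR_POLICIES:
        raise ValidationError(
            f"unknown censoring policy {policy!r}; choose from {CENSOR_POLICIES}"
        )
    df = table.df.copy()
    if policy == "zero":
        df.loc[df["state"] == "censored", "value"] = 0.0
    elif policy == "half_lod":
        df.loc[df["state"] == "censored", "value"] /= 2.0
    # policy == "lod": the stored LOD already stands in
    return df.drop(columns="state")


# ---------------------------------------------------------------------------
# I/O

def _read_csv(path_or_buf, **kw) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, comment="#", dtype=str, skip_blank_lines=True, **kw)
    if df.empty:
        raise ValidationError("file contains no data rows")
    return df


def load_concentration_table(
    path: str | Path | io.TextIOBase, schema: str = "long"
) -> ConcentrationTable:
    """Read a concentration CSV and return a validated, normalized table.

    ``long`` schema: columns ``sample_id, compartment, element, value,
    unit`` with censoring written as ``<LOD`` in the value column.
    ``wide`` schema: one row per (sample, compartment), one column per
    element, preceded by a sidecar header line
    ``#units: El=unit,El=unit,...``.
    """
    if schema == "long":
        df = _read_csv(path)
        needed = {"sample_id", "compartment", "element", "value", "unit"}
        if not needed <= set(df.columns):
            raise ValidationError(f"long schema needs columns {sorted(needed)}")
        records = df
    elif schema == "wide":
        records = _read_wide(path)
    else:
        raise ValidationError(f"unknown schema {schema!r}")

    rows = []
    for r in records.itertuples(index=False):
        try:
            cv = parse_censored(r.value)
        except ValidationError as exc:
            raise ValidationError(
                f"row ({r.sample_id}, {r.compartment}, {r.element}): {exc}"
            ) from None
        rows.append(
            (r.sample_id, r.compartment, r.element, cv.state, cv.value, r.unit)
        )
    table = ConcentrationTable(
        pd.DataFrame(rows, columns=list(ConcentrationTable.REQUIRED))
    )
    return table.normalize_units()


def _read_wide(path) -> pd.DataFrame:
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    unit_map: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#units:"):
            for item in line[len("#units:"):].split(","):
                el, _, unit = item.strip().partition("=")
                unit_map[el.strip()] = unit.strip()
        elif not line.startswith("#"):
            body_lines.append(line)
    if not unit_map:
        raise ValidationError("wide schema requires a '#units:' sidecar line")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), dtype=str)
    if not {"sample_id", "compartment"} <= set(df.columns):
        raise ValidationError("wide schema needs sample_id and compartment columns")
    long = df.melt(
        id_vars=["sample_id", "compartment"], var_name="element", value_name="value"
    )
    missing_units = set(long["element"]) - set(unit_map)
    if missing_units:
        raise ValidationError(f"no unit declared for: {sorted(missing_units)}")
    long["unit"] = long["element"].map(unit_map)
    long["value"] = long["value"].fillna("*****")
    return long


def load_toxicity_references(path: str | Path) -> pd.DataFrame:
    """Read ``element,rfd_mg_kg_day,slope_factor`` into a per-element frame.

    Returns a DataFrame indexed by element with float columns
    ``rfd_mg_kg_day`` and ``slope_factor``; absent cells become NaN
    (meaning the reference value is not determined, not zero).
    """
    df = _read_csv(path)
    needed = {"element", "rfd_mg_kg_day", "slope_factor"}
    if not needed <= set(df.columns):
        raise ValidationError(f"toxicity table needs columns {sorted(needed)}")
    bad_el = set(df["element"]) - set(ELEMENTS)
    if bad_el:
        raise ValidationError(f"unknown element symbols: {sorted(bad_el)}")
    if df["element"].duplicated().any():
        raise ValidationError("duplicate element rows in toxicity table")
    out = df.set_index("element")[["rfd_mg_kg_day", "slope_factor"]].apply(
        pd.to_numeric, errors="raise"
    )
    if (out["rfd_mg_kg_day"].dropna() <= 0).any():
        raise ValidationError("RfD must be strictly positive where present")
    if (out["slope_factor"].dropna() < 0).any():
        raise ValidationError("slope factor must be non-negative where present")
    return out


def load_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read ``sample_id,tobacco_type,label`` sample annotations."""
    df = _read_csv(path)
    needed = {"sample_id", "tobacco_type"}
    if not needed <= set(df.columns):
        raise ValidationError(f"meta table needs columns {sorted(needed)}")
    bad = set(df["tobacco_type"]) - {"maassel", "traditional"}
    if bad:
        raise ValidationError(f"tobacco_type must be maassel/traditional, got {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in meta table")
    if "label" not in df.columns:
        df["label"] = df["sample_id"]
    return df[["sample_id", "tobacco_type", "label"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bundled study fixtures

def _fixture(name: str):
    return resources.files("hookahrisk.data").joinpath(name)


def load_study_tables() -> ConcentrationTable:
    """The transcribed study data: 5 tobaccos × 29 elements × 3 compartments,
    unit-normalized."""
    parts = [
        load_concentration_table(_fixture(n))
        for n in ("raw_tobacco.csv", "tobacco_ash.csv", "bowl_water.csv")
    ]
    table = parts[0].concat(parts[1]).concat(parts[2])
    return table


def load_study_meta() -> pd.DataFrame:
    with resources.as_file(_fixture("sample_meta.csv")) as p:
        return load_sample_meta(p)


def load_toxicity_fixture() -> pd.DataFrame:
    with resources.as_file(_fixture("toxicity_references.csv")) as p:
        return load_toxicity_references(p)


def load_lod_fixture() -> pd.Series:
    """Instrument detection limits in the measured solution (µg/L), by element."""
    with resources.as_file(_fixture("lod_icpms.csv")) as p:
        df = _read_csv(p)
    return pd.to_numeric(df.set_index("element")["lod_ug_l"])
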
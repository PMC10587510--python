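"""Per-sample elemental totals and macro-element composition shares.

Across tobaccos the bulk of the elemental mass sits in five macro-elements
(Ca, K, Na, Mg, P); this module computes each compartment's total
concentration, the per-element fractions of that total, and the joint
"main share" of the five macro-elements, on the mg/kg (solids) or mg/L
(water) scale after censoring substitution.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    ELEMENTS,
    MAIN_ELEMENTS,
    ConcentrationTable,
    ValidationError,
    substitute_censored,
)

__all__ = [
    "element_totals",
    "main_element_share",
    "composition_report",
    "plot_composition",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding with ties away from zero (5 rounds up), as tables
    in the trade print it; full precision is kept internally elsewhere."""
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def _substituted(table: ConcentrationTable, policy: str) -> pd.DataFrame:
    df = substitute_censored(table, policy)
    return df.dropna(subset=["value"])  # missing cells are excluded from sums


def element_totals(table: ConcentrationTable, policy: str = "zero") -> pd.DataFrame:
    """Total concentration per (sample, compartment).

    The total is the sum of substituted values over non-missing elements,
    in mg/kg for solids and mg/L for water. A (sample, compartment) group
    whose every element is missing raises, rather than reporting a
    spurious zero.
    """
    df = _substituted(table, policy)
    empties = (
        table.df.groupby(["sample_id", "compartment"], sort=False)["state"]
        .apply(lambda s: (s == "missing").all())
    )
    if empties.any():
        bad = [f"{s}/{c}" for (s, c), e in empties.items() if e]
        raise ValidationError(f"no non-missing elements in: {', '.join(bad)}")
    out = (
        df.groupby(["sample_id", "compartment"], sort=False)["value"]
        .sum()
        .rename("total")
        .reset_index()
    )
    return out


def main_element_share(
    table: ConcentrationTable,
    sample_id: str,
    compartment: str,
    policy: str = "zero",
) -> float:
    """Percent of the compartment total carried by Ca, K, Na, Mg and P.

    100 × Σ_{e ∈ {Ca,K,Na,Mg,P}} c_e / Σ_all c_e, at full precision
    (round to one decimal for display). Raises when the total is zero.
    """
    df = _substituted(table.select(sample_id=sample_id, compartment=compartment), policy)
    total = df["value"].sum()
    if total <= 0:
        raise ValidationError(
            f"total concentration of {sample_id}/{compartment} is zero; "
            "main-element share undefined"
        )
    main = df.loc[df["element"].isin(MAIN_ELEMENTS), "value"].sum()
    return float(100.0 * main / total)


def composition_report(
    table: ConcentrationTable,
    policy: str = "zero",
    compartments: list[str] | None = None,
) -> pd.DataFrame:
    """One composition profile per (sample, compartment).

    Columns: ``total``, ``main_share`` (percent), and ``frac_<El>`` — the
    per-element fraction of the total over non-missing elements (fractions
    sum to 1 per row). Missing elements yield NaN fractions.
    """
    if compartments is not None:
        keep = table.df["compartment"].isin(compartments)
        if not keep.any():
            return pd.DataFrame(
                columns=["sample_id", "compartment", "total", "main_share"]
            )
        table = ConcentrationTable(table.df[keep])
    totals = element_totals(table, policy)
    df = _substituted(table, policy)
    wide = df.pivot_table(
        index=["sample_id", "compartment"], columns="element", values="value"
    )
    wide = wide.reindex(columns=[e for e in ELEMENTS if e in wide.columns])
    fractions = wide.div(wide.sum(axis=1), axis=0)
    fractions.columns = [f"frac_{e}" for e in fractions.columns]
    report = totals.set_index(["sample_id", "compartment"]).join(fractions)
    main_cols = [f"frac_{e}" for e in MAIN_ELEMENTS if f"frac_{e}" in report.columns]
    report.insert(1, "main_share", 100.0 * report[main_cols].sum(axis=1))
    return report.reset_index()


def plot_composition(
    report: pd.DataFrame, compartment: str, out_dir: str | Path
) -> Path:
    """Stacked-bar figure of the five macro-element fractions plus "other"
    for one compartment; returns the written PNG path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report[report["compartment"] == compartment]
    if sub.empty:
        raise ValidationError(f"report has no rows for compartment {compartment!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(sub))
    for el in MAIN_ELEMENTS:
        vals = sub.get(f"frac_{el}", pd.Series(0.0, index=sub.index)).fillna(0.0).to_numpy()
        ax.bar(sub["sample_id"], 100 * vals, bottom=bottom, label=el)
        bottom += 100 * vals
    ax.bar(sub["sample_id"], 100 - bottom, bottom=bottom, label="other", color="0.8")
    ax.set_ylabel("share of total concentration (%)")
    ax.set_title(f"Macro-element composition — {compartment}")
    ax.legend(ncols=3, fontsize=8)
    path = out_dir / f"composition_{compartment}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
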
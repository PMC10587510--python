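"""Friedman rank test and the raw-vs-ash / traditional-vs-Maassel
comparison logic.

The Friedman test compares k related treatments across n blocks: each
block's measurements are replaced by within-block ranks (mid-ranks on
ties) and the test statistic

    Q = 12 / (n k (k+1)) · Σ_j R_j² − 3 n (k+1)

(with the standard tie correction, dividing by
1 − Σ(t³−t) / (n k (k³−k)) over tie groups) is referred to a χ²
distribution with k−1 degrees of freedom, or to the exact permutation
distribution over all (k!)ⁿ equally likely within-block orderings for
small designs.

The statistic is implemented here from first principles because the
ranking-and-correction arithmetic is the analysis this package exists to
make reproducible; tests cross-check it against an independent library
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ConcentrationTable, ValidationError, substitute_censored
from .composition import element_totals

__all__ = [
    "BlockDesign",
    "FriedmanResult",
    "friedman_statistic",
    "friedman_pvalue",
    "friedman_test",
    "compare_conditions",
    "EXACT_LIMIT",
]

#: Largest n·k for which exact permutation p-values are enumerated.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class BlockDesign:
    """n blocks × k treatments of related measurements, no missing cells."""

    data: np.ndarray
    block_labels: tuple[str, ...] = ()
    treatment_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("block design must be a 2-D matrix")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise ValidationError("need at least 2 blocks and 2 treatments")
        if not np.isfinite(arr).all():
            raise ValidationError("block design cannot contain missing cells")
        object.__setattr__(self, "data", arr)
        if self.block_labels and len(self.block_labels) != n:
            raise ValidationError("block label count mismatch")
        if self.treatment_labels and len(self.treatment_labels) != k:
            raise ValidationError("treatment label count mismatch")

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    degenerate: bool = False  # every block completely tied; Q defined as 0
    p_value: float | None = None
    method: str | None = None


def _within_block_ranks(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, data)  # mid-ranks on ties


def friedman_statistic(design: BlockDesign) -> FriedmanResult:
    """Tie-corrected Friedman statistic Q with df = k − 1.

    An all-tied design (the tie-correction denominator vanishes) returns
    Q = 0 with the ``degenerate`` flag rather than 0/0.
    """
    data = design.data
    n, k = data.shape
    ranks = _within_block_ranks(data)
    col_sums = ranks.sum(axis=0)
    q_uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        return FriedmanResult(0.0, k - 1, degenerate=True)
    return FriedmanResult(q_uncorrected / correction, k - 1)


def _exact_null_distribution(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All Friedman statistics over the (k!)ⁿ equally likely rank tables."""
    perms = list(permutations(range(1, k + 1)))
    qs = []
    for combo in product(perms, repeat=n):
        col_sums = np.sum(combo, axis=0)
        q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
        qs.append(q)
    qs = np.asarray(qs)
    return qs, np.full(len(qs), 1.0 / len(qs))


def friedman_pvalue(
    statistic: float,
    n_blocks: int,
    n_treatments: int,
    method: str = "chisq",
) -> float:
    """Upper-tail p-value for an observed Friedman statistic.

    ``chisq``: χ² survival function with k−1 degrees of freedom.
    ``exact``: fraction of all (k!)ⁿ within-block rank permutations whose
    statistic is ≥ the observed one; only for n·k ≤ 12.
    """
    if statistic < 0:
        raise ValidationError("Friedman statistic cannot be negative")
    if method == "chisq":
        return float(stats.chi2.sf(statistic, n_treatments - 1))
    if method == "exact":
        if n_blocks * n_treatments > EXACT_LIMIT:
            raise ValidationError(
                f"exact enumeration limited to n*k <= {EXACT_LIMIT}; use method='chisq'"
            )
        qs, probs = _exact_null_distribution(n_blocks, n_treatments)
        return float(probs[qs >= statistic - 1e-12].sum())
    raise ValidationError(f"unknown method {method!r}")


def friedman_test(design: BlockDesign, method: str = "chisq") -> FriedmanResult:
    """Statistic and p-value in one call."""
    res = friedman_statistic(design)
    p = 1.0 if res.degenerate else friedman_pvalue(
        res.statistic, design.n_blocks, design.n_treatments, method
    )
    return FriedmanResult(res.statistic, res.df, res.degenerate, p, method)


# ---------------------------------------------------------------------------
# Study comparison logic

def _direction(label_hi: str, label_lo: str, diff: float) -> str:
    if diff > 0:
        return f"{label_hi}>{label_lo}"
    if diff < 0:
        return f"{label_lo}>{label_hi}"
    return "none"


def _interaction_note(med_maassel: float, med_traditional: float) -> str:
    """Descriptive raw→ash trend per tobacco type, from median ash−raw."""
    def word(d: float) -> str:
        return "rising" if d > 0 else ("falling" if d < 0 else "flat")

    wm, wt = word(med_maassel), word(med_traditional)
    if wm == wt:
        return f"raw-to-ash direction is {wm} for both types"
    return f"the direction of Maassel is {wm} while of traditional is {wt}"


def compare_conditions(
    table: ConcentrationTable,
    meta: pd.DataFrame,
    alpha: float = 0.10,
    policy: str = "zero",
) -> pd.DataFrame:
    """Per-element raw-vs-ash and traditional-vs-Maassel verdicts, plus a
    total-concentration row.

    For each element, the raw/ash contrast is a Friedman test with samples
    as blocks and the two compartments as treatments (exact permutation
    p for these small designs). The tobacco-type contrast is unpaired, so
    it uses an exact two-sample rank-sum test, pooling each sample's raw
    and ash values so both time points inform the comparison (with only a
    handful of samples per type this pooling is what makes the contrast
    resolvable at all; it treats within-sample compartments as replicate
    burden measurements, a pragmatic choice documented in the methods
    note). Direction labels come from group medians and are reported only
    at p ≤ alpha. The interaction note is descriptive text from the
    per-type median raw→ash change, not a formal test.
    """
    needed = {"raw", "ash"}
    if not needed <= set(table.df["compartment"]):
        raise ValidationError("comparison needs both raw and ash records")
    meta = meta.set_index("sample_id")["tobacco_type"]
    unknown = set(table.df["sample_id"]) - set(meta.index)
    if unknown:
        raise ValidationError(f"samples without metadata: {sorted(unknown)}")

    df = substitute_censored(table, policy)
    df = df[df["compartment"].isin(needed)].dropna(subset=["value"])
    df["tobacco_type"] = df["sample_id"].map(meta)

    group_sizes = meta.value_counts()
    small_groups = group_sizes[group_sizes < 2].index.tolist()

    totals = element_totals(
        ConcentrationTable(table.df[table.df["compartment"].isin(needed)]), policy
    ).rename(columns={"total": "value"})
    totals["element"] = "Total concentration"
    totals["tobacco_type"] = totals["sample_id"].map(meta)

    rows = []
    elements = [e for e in df["element"].unique()] + ["Total concentration"]
    for element in elements:
        sub = totals if element == "Total concentration" else df[df["element"] == element]
        wide = sub.pivot_table(index="sample_id", columns="compartment", values="value")
        wide = wide.dropna()
        if len(wide) < 2 or wide.shape[1] < 2:
            rows.append((element, np.nan, np.nan, "none", "none", "skipped: too few paired samples"))
            continue

        design = BlockDesign(
            wide[["raw", "ash"]].to_numpy(),
            block_labels=tuple(wide.index),
            treatment_labels=("raw", "ash"),
        )
        method = "exact" if design.n_blocks * 2 <= EXACT_LIMIT else "chisq"
        time_res = friedman_test(design, method=method)
        diff_time = float((wide["ash"] - wide["raw"]).median())
        direction_time = (
            _direction("ash", "raw", diff_time)
            if time_res.p_value is not None and time_res.p_value <= alpha
            else "none"
        )

        if small_groups:
            p_type, direction_type = np.nan, "none"
            note = f"skipped type contrast: group(s) {small_groups} have <2 samples"
        else:
            trad = sub.loc[sub["tobacco_type"] == "traditional", "value"]
            maas = sub.loc[sub["tobacco_type"] == "maassel", "value"]
            if len(trad) < 2 or len(maas) < 2:
                p_type, direction_type, note = np.nan, "none", "skipped type contrast: too few values"
            else:
                mw = stats.mannwhitneyu(trad, maas, alternative="two-sided", method="exact")
                p_type = float(mw.pvalue)
                direction_type = (
                    _direction("traditional", "maassel", float(trad.median() - maas.median()))
                    if p_type <= alpha
                    else "none"
                )
                note = ""
        if not note:
            med_m = float(
                (wide["ash"] - wide["raw"])[
                    [s for s in wide.index if meta[s] == "maassel"]
                ].median()
            ) if any(meta[s] == "maassel" for s in wide.index) else 0.0
            med_t = float(
                (wide["ash"] - wide["raw"])[
                    [s for s in wide.index if meta[s] == "traditional"]
                ].median()
            ) if any(meta[s] == "traditional" for s in wide.index) else 0.0
            note = _interaction_note(med_m, med_t)

        rows.append(
            (element, time_res.p_value, p_type, direction_type, direction_time, note)
        )

    out = pd.DataFrame(
        rows,
        columns=["element", "p_value", "p_value_type", "direction_type", "direction_time", "note"],
    )
    return out
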
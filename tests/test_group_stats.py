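"""Friedman statistic, exact/chi-square p-values, and study comparisons.

The oracles here are deliberately independent of the implementation:
rank sums are rebuilt by pairwise comparison counting, and the exact null
distribution is re-enumerated with itertools inside the test.
"""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare

from hookahrisk.core_data import ConcentrationTable, ValidationError
from hookahrisk.group_stats import (
    BlockDesign,
    compare_conditions,
    friedman_pvalue,
    friedman_statistic,
    friedman_test,
)
from hookahrisk.synthetic import GeneratorConfig, generate_study


def oracle_statistic(data):
    """Brute-force Friedman Q: mid-ranks by comparison counting, the
    textbook rank-sum formula, and the tie correction term by term."""
    data = np.asarray(data, float)
    n, k = data.shape
    ranks = np.zeros_like(data)
    for i in range(n):
        for j in range(k):
            less = sum(1 for v in data[i] if v < data[i, j])
            equal = sum(1 for v in data[i] if v == data[i, j])
            ranks[i, j] = less + (equal + 1) / 2.0
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * sum(r * r for r in rj) - 3.0 * n * (k + 1)
    ties = sum(
        sum(np.sum(data[i] == v) ** 3 - np.sum(data[i] == v)
            for v in set(data[i]))
        for i in range(n)
    )
    denom = 1.0 - ties / (n * (k**3 - k))
    return 0.0 if denom <= 0 else q / denom


def oracle_exact_p(q_obs, n, k):
    perms = list(permutations(range(1, k + 1)))
    hits = total = 0
    for combo in product(perms, repeat=n):
        rj = np.sum(combo, axis=0)
        q = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
        hits += q >= q_obs - 1e-12
        total += 1
    return hits / total


class TestFriedmanStatistic:
    def test_consistent_ordering_3x3(self):
        """Three blocks all ranked (1,2,3): rank sums (3,6,9) give Q = 6."""
        d = BlockDesign(np.array([[1, 2, 3], [4, 5, 6], [0.1, 0.2, 0.3]]))
        res = friedman_statistic(d)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_identical_columns_give_zero(self):
        d = BlockDesign(np.ones((4, 3)))
        res = friedman_statistic(d)
        assert res.statistic == 0.0
        assert res.degenerate
        assert friedman_test(d).p_value == 1.0

    @pytest.mark.parametrize("n,k", [(2, 2), (3, 2), (5, 2), (3, 3), (4, 3), (2, 4)])
    def test_matches_bruteforce_oracle_small_designs(self, n, k):
        rng = np.random.default_rng(n * 100 + k)
        for _ in range(20):
            data = rng.integers(0, 4, size=(n, k)).astype(float)  # forces ties
            ours = friedman_statistic(BlockDesign(data)).statistic
            assert ours == pytest.approx(oracle_statistic(data), abs=1e-10)

    @pytest.mark.parametrize("shape", [(6, 3), (5, 4), (8, 5)])
    def test_matches_library_implementation(self, shape):
        rng = np.random.default_rng(42)
        for _ in range(10):
            data = rng.normal(size=shape)
            data[rng.random(shape) < 0.3] = 0.0  # inject ties
            ours = friedman_statistic(BlockDesign(data)).statistic
            ref = friedmanchisquare(*data.T).statistic
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_monotone_within_block_transform(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 3))
        q0 = friedman_statistic(BlockDesign(data)).statistic
        q1 = friedman_statistic(BlockDesign(np.exp(data))).statistic
        q2 = friedman_statistic(BlockDesign(data**3 + 7)).statistic
        assert q0 == pytest.approx(q1) == pytest.approx(q2)

    def test_no_ties_correction_is_identity(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(6, 3))
        ours = friedman_statistic(BlockDesign(data)).statistic
        # uncorrected formula straight from the rank sums
        ranks = np.apply_along_axis(
            lambda r: np.argsort(np.argsort(r)) + 1.0, 1, data
        )
        rj = ranks.sum(axis=0)
        n, k = data.shape
        q = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert ours == pytest.approx(q)

    @pytest.mark.parametrize(
        "bad", [np.ones((1, 3)), np.ones((3, 1)), np.full((3, 3), np.nan)]
    )
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(ValidationError):
            BlockDesign(bad)


class TestFriedmanPValue:
    def test_chisq_hand_worked(self):
        assert friedman_pvalue(6.0, 3, 3, "chisq") == pytest.approx(0.0498, abs=2e-4)

    def test_zero_statistic_gives_one(self):
        assert friedman_pvalue(0.0, 3, 3, "chisq") == pytest.approx(1.0)
        assert friedman_pvalue(0.0, 3, 3, "exact") == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle_2x3(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            data = rng.normal(size=(2, 3))
            q = friedman_statistic(BlockDesign(data)).statistic
            assert friedman_pvalue(q, 2, 3, "exact") == pytest.approx(
                oracle_exact_p(q, 2, 3)
            )

    @pytest.mark.parametrize("n,k", [(5, 2), (3, 4), (4, 3)])
    def test_exact_matches_enumeration_oracle(self, n, k):
        for q in (0.0, 1.0, 3.5, 6.0):
            assert friedman_pvalue(q, n, k, "exact") == pytest.approx(
                oracle_exact_p(q, n, k)
            )

    def test_exact_refuses_large_designs(self):
        with pytest.raises(ValidationError, match="chisq"):
            friedman_pvalue(1.0, 5, 3, "exact")

    def test_chisq_approximation_sanity_band_4x3_tail(self):
        """chi-square and exact p agree within 0.05 absolute on 4x3
        designs in the rejection-relevant tail (exact p <= 0.15).

        Across the whole p range the chi-square approximation undershoots
        the exact permutation p by up to ~0.18 at this n, so the sanity
        band is meaningful, and asserted, only where decisions are made.
        """
        checked = 0
        for q in np.arange(0.0, 8.1, 0.5):
            p_ex = friedman_pvalue(q, 4, 3, "exact")
            if p_ex <= 0.15:
                p_chi = friedman_pvalue(q, 4, 3, "chisq")
                assert abs(p_chi - p_ex) <= 0.05, (q, p_chi, p_ex)
                checked += 1
        assert checked >= 3


class TestCompareConditions:
    def test_study_verdict_table_shape(self, study_table, study_meta):
        v = compare_conditions(study_table, study_meta, alpha=0.10)
        assert len(v) == 30  # 29 elements + total concentration
        assert v["element"].iloc[-1] == "Total concentration"
        defined = v["p_value"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()

    def test_study_total_concentration_direction(self, study_table, study_meta):
        """Traditional tobaccos carry more total elemental mass."""
        v = compare_conditions(study_table, study_meta, alpha=0.10)
        total = v[v["element"] == "Total concentration"].iloc[0]
        assert total["direction_type"] == "traditional>maassel"

    def test_duplicated_identical_samples_yield_no_directions(self):
        rows = []
        for s in ("a1", "a2", "b1", "b2"):
            for comp in ("raw", "ash"):
                rows.append((s, comp, "Ca", "observed", 10.0, "mg/kg"))
        table = ConcentrationTable(
            pd.DataFrame(rows, columns=["sample_id", "compartment", "element",
                                        "state", "value", "unit"])
        )
        meta = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "tobacco_type": ["maassel", "maassel", "traditional", "traditional"],
             "label": ["a1", "a2", "b1", "b2"]}
        )
        v = compare_conditions(table, meta)
        assert (v["p_value"].dropna() == 1.0).all()
        assert (v["direction_type"] == "none").all()
        assert (v["direction_time"] == "none").all()

    def test_planted_type_effect_detected(self):
        cfg = GeneratorConfig(
            seed=11, n_per_type=5, elements=("Na", "Ca"), log_mean=3.0,
            log_sd=0.5, type_effect={"Na": 5.0, "Ca": 1.0}, lod=0.0,
        )
        table, meta, _ = generate_study(cfg)
        v = compare_conditions(table, meta, alpha=0.10).set_index("element")
        assert v.loc["Na", "direction_type"] == "traditional>maassel"

    def test_single_sample_group_skipped_with_warning_note(self, study_table):
        meta = pd.DataFrame(
            {"sample_id": study_table.samples,
             "tobacco_type": ["maassel"] * 4 + ["traditional"],
             "label": study_table.samples}
        )
        v = compare_conditions(study_table, meta)
        assert (v["direction_type"] == "none").all()
        assert v["note"].str.contains("skipped type contrast").all()
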
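"""Instrument selection: p-screen, clumping, R²/F formulas, weak-IV filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.errors import MissingEafError
from mrscreen.iv_selection import (
    build_instrument_set,
    clump,
    compute_f,
    compute_ld_from_dosages,
    compute_r2,
    drop_weak_instruments,
    filter_by_pvalue,
    joint_f,
    select_instruments,
)
from mrscreen.sumstats import LdTable
from tests.conftest import make_table


class TestPvalueFilter:
    def test_strict_boundary(self):
        t = make_table([{"pval": 1e-6}, {"pval": 1e-5}, {"pval": 1e-4}])
        kept = filter_by_pvalue(t, 1e-5)
        assert kept.df["pval"].tolist() == [1e-6]

    def test_empty_table_passes_through(self):
        t = make_table([{}]).subset([])
        assert len(filter_by_pvalue(t, 1e-5)) == 0

    def test_matches_brute_force_enumeration(self, rng):
        pvals = rng.uniform(size=500)
        t = make_table([{"pval": p} for p in pvals])
        kept = filter_by_pvalue(t, 0.05)
        assert len(kept) == int(np.sum(pvals < 0.05))
        assert set(kept.df["pval"]) == {p for p in pvals if p < 0.05}


def brute_force_clump(table, ld, r2_max, window_kb):
    """Independent greedy reference: explicit list bookkeeping, no shortcuts."""
    remaining = table.df.sort_values(["pval", "chrom", "pos"]).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["snp_id"])
        survivors = []
        for cand in remaining:
            same_chrom = cand["chrom"] == index["chrom"]
            in_window = abs(cand["pos"] - index["pos"]) <= window_kb * 1000
            if same_chrom and in_window and ld.r2(index["snp_id"], cand["snp_id"]) >= r2_max:
                continue
            survivors.append(cand)
        remaining = survivors
    return set(kept)


class TestClump:
    def test_correlated_neighbours_pruned_keeping_best_p(self):
        t = make_table([
            {"pval": 1e-8, "pos": 1000},
            {"pval": 1e-6, "pos": 6000},
        ])
        ld = LdTable([("rs1", "rs2", 0.9)])
        kept = clump(t, ld, r2_max=0.001, window_kb=10)
        assert kept.df["snp_id"].tolist() == ["rs1"]

    def test_window_never_spans_chromosomes(self):
        t = make_table([
            {"pval": 1e-8, "chrom": "1", "pos": 1000},
            {"pval": 1e-6, "chrom": "2", "pos": 1000},
        ])
        ld = LdTable([("rs1", "rs2", 0.9)])
        assert len(clump(t, ld, 0.001, 10_000)) == 2

    def test_missing_ld_pairs_treated_independent(self):
        t = make_table([{"pval": 1e-8, "pos": 1000}, {"pval": 1e-6, "pos": 2000}])
        assert len(clump(t, LdTable(), 0.001, 10_000)) == 2

    def test_matches_brute_force_oracle_on_ld_blocks(self, rng):
        # 50 SNPs in 5 LD blocks of 10, block-mates correlated, others not
        rows, pairs = [], []
        for i in range(50):
            block = i // 10
            rows.append({"pval": float(rng.uniform()), "chrom": str(block % 2 + 1),
                         "pos": 100_000 * block + 1000 * i})
        for i in range(50):
            for j in range(i + 1, 50):
                if i // 10 == j // 10:
                    pairs.append((f"rs{i + 1}", f"rs{j + 1}", float(rng.uniform(0.2, 1.0))))
        t = make_table(rows)
        ld = LdTable(pairs)
        kept = clump(t, ld, r2_max=0.3, window_kb=10_000)
        assert set(kept.df["snp_id"]) == brute_force_clump(t, ld, 0.3, 10_000)

    def test_output_mutually_below_threshold_within_windows(self, rng):
        rows, pairs = [], []
        for i in range(30):
            rows.append({"pval": float(rng.uniform()), "pos": 1000 * (i + 1)})
        for i in range(30):
            for j in range(i + 1, 30):
                pairs.append((f"rs{i + 1}", f"rs{j + 1}", float(rng.uniform())))
        t = make_table(rows)
        ld = LdTable(pairs)
        kept = clump(t, ld, r2_max=0.4, window_kb=10_000)
        ids = kept.df["snp_id"].tolist()
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                assert ld.r2(ids[a], ids[b]) < 0.4


class TestLdFromDosages:
    def test_identical_and_independent_columns(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        # exactly-uncorrelated pair by construction
        a = np.array([0.0, 2.0, 0.0, 2.0])
        b = np.array([0.0, 0.0, 2.0, 2.0])
        ld = compute_ld_from_dosages(np.column_stack([col, col]), ["s1", "s2"])
        assert ld.r2("s1", "s2") == pytest.approx(1.0)
        ld2 = compute_ld_from_dosages(np.column_stack([a, b]), ["s1", "s2"])
        assert ld2.r2("s1", "s2") == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_correlation_formula(self, rng):
        g = rng.integers(0, 3, size=(100, 3)).astype(float)
        ld = compute_ld_from_dosages(g, ["a", "b", "c"])
        for i, j, x, y in [(0, 1, "a", "b"), (0, 2, "a", "c"), (1, 2, "b", "c")]:
            xi, yj = g[:, i], g[:, j]
            num = np.sum((xi - xi.mean()) * (yj - yj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((yj - yj.mean()) ** 2))
            assert ld.r2(x, y) == pytest.approx((num / den) ** 2, rel=1e-12)

    def test_zero_variance_column_pairs_omitted(self):
        g = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        ld = compute_ld_from_dosages(g, ["flat", "var"])
        assert ld.dropped_snps == ["flat"]
        assert ld.r2("flat", "var") == 0.0  # absent => independent


class TestVarianceExplained:
    def test_zero_beta_zero_r2(self):
        assert compute_r2(0.0, 0.3, 0.01, 8299) == 0.0

    def test_hand_evaluation_of_formula(self):
        # 2·0.1²·0.25 = 0.005; denominator 0.005 + 2·0.01²·8299·0.25 = 0.41995
        assert compute_r2(0.1, 0.5, 0.01, 8299) == pytest.approx(0.005 / 0.41995, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        beta=st.floats(-2, 2),
        eaf=st.floats(0.01, 0.99),
        se=st.floats(1e-4, 1.0),
        n=st.integers(10, 10**6),
    )
    def test_symmetric_in_eaf_and_bounded(self, beta, eaf, se, n):
        r2 = compute_r2(beta, eaf, se, n)
        assert r2 == pytest.approx(compute_r2(beta, 1 - eaf, se, n), rel=1e-12)
        assert 0 <= r2 < 1

    def test_missing_eaf_is_hard_error(self):
        with pytest.raises(MissingEafError):
            compute_r2(0.1, np.nan, 0.01, 8299)


class TestFStatistic:
    def test_zero_r2_gives_zero(self):
        assert compute_f(0.0, 1000, 1) == 0.0

    def test_hand_evaluation(self):
        assert compute_f(0.01, 1002, 1) == pytest.approx(0.01 * 1000 / 0.99, rel=1e-12)

    def test_strictly_increasing_in_r2(self):
        grid = np.linspace(0, 0.9, 50)
        f = compute_f(grid, 5000, 1)
        assert np.all(np.diff(f) > 0)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            compute_f(0.1, 2, 1)


class TestWeakInstrumentFilter:
    def _set_with_f(self, f_targets, n=8299):
        # invert F = R2(n-2)/(1-R2) and R2 = beta^2/(beta^2 + se^2 n) for fixtures
        rows = []
        for f in f_targets:
            r2 = f / (n - 2 + f)
            se = 0.01
            beta = np.sqrt(r2 * se**2 * n / (1 - r2))
            rows.append({"beta": beta, "se": se, "eaf": 0.3, "n": n})
        return build_instrument_set(make_table(rows))

    def test_boundary_f_equal_10_is_retained(self):
        iset = self._set_with_f([9.9, 10.0, 21.2])
        kept = drop_weak_instruments(iset, 10.0)
        assert kept.metrics["f_stat"].round(6).tolist() == [10.0, 21.2]
        assert kept.selection_log["weak_instruments"] == 1

    def test_empty_set_passes_through(self):
        iset = build_instrument_set(make_table([{}]).subset([]))
        assert drop_weak_instruments(iset, 10.0).n_snp == 0

    def test_matches_brute_force_enumeration(self, rng):
        targets = rng.uniform(1, 40, size=200)
        iset = self._set_with_f(targets)
        kept = drop_weak_instruments(iset, 10.0)
        expected = {s for s, f in zip(iset.metrics["snp_id"], iset.metrics["f_stat"])
                    if f >= 10.0}
        assert set(kept.table.df["snp_id"]) == expected

    def test_threshold_equivalence_in_r2_space(self, rng):
        # per-SNP k=1: F >= f_min  <=>  R2 >= f_min / (N - 2 + f_min)
        iset = self._set_with_f(rng.uniform(5, 20, size=100))
        n = 8299
        f_min = 10.0
        by_f = iset.metrics["f_stat"] >= f_min
        by_r2 = iset.metrics["r2"] >= f_min / (n - 2 + f_min)
        assert (by_f == by_r2).all()

    def test_joint_f_uses_set_size_as_k(self):
        iset = self._set_with_f([20.0, 20.0, 20.0])
        n = 8299
        r2_tot = iset.metrics["r2"].sum()
        assert joint_f(iset) == pytest.approx(r2_tot * (n - 4) / (3 * (1 - r2_tot)))

    def test_metrics_require_eaf(self):
        t = make_table([{"eaf": np.nan}])
        with pytest.raises(MissingEafError):
            build_instrument_set(t)


def test_selection_is_row_order_invariant(rng):
    rows = [{"pval": float(p), "pos": 1000 * (i + 1)}
            for i, p in enumerate(rng.uniform(1e-8, 1e-3, size=40))]
    t = make_table(rows)
    ld = LdTable([(f"rs{i}", f"rs{i + 1}", 0.5) for i in range(1, 40)])
    ref = select_instruments(t, ld, pval_threshold=1e-4, clump_r2=0.3)
    perm = t.df.iloc[rng.permutation(len(t.df))].reset_index(drop=True)
    shuffled = select_instruments(
        type(t)(t.trait_id, t.trait_type, perm), ld, pval_threshold=1e-4, clump_r2=0.3
    )
    assert set(ref.table.df["snp_id"]) == set(shuffled.table.df["snp_id"])
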
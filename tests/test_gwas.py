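import numpy as np
import pandas as pd
import pytest

from coloc_longevity import (
    SignificancePolicy,
    add_d_scores,
    assign_bins,
    bonferroni_threshold,
    classify_coding,
    combine_duplicate_snps,
    compute_D,
    select_significant,
)

from conftest import gene_frame, snp_frame


class TestComputeD:
    def test_identical_groups_give_zero(self):
        h = np.full(8, 1 / 8)
        assert compute_D(h, h) == 0.0

    def test_closed_form_uniform_difference(self):
        # every founder differs by 0.1 over n=8: D = 100*sqrt(8*0.01/8) = 10
        ho = np.full(8, 0.125) + 0.05
        hy = np.full(8, 0.125) - 0.05
        assert compute_D(ho, hy) == pytest.approx(10.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ho = rng.dirichlet(np.ones(5))
            hy = rng.dirichlet(np.ones(5))
            expected = 100.0 * np.sqrt(
                sum((a - b) ** 2 for a, b in zip(ho, hy)) / 5
            )
            assert compute_D(ho, hy) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        ho, hy = rng.dirichlet(np.ones(6)), rng.dirichlet(np.ones(6))
        perm = rng.permutation(6)
        assert compute_D(ho, hy) == pytest.approx(compute_D(ho[perm], hy[perm]), abs=1e-12)

    def test_difference_scaling(self):
        # shrinking all frequency differences by c shrinks D by c
        ho = np.array([0.3, 0.3, 0.2, 0.2])
        hy = np.array([0.25, 0.35, 0.25, 0.15])
        d_full = compute_D(ho, hy)
        for c in (0.5, 0.25):
            hy_c = ho - c * (ho - hy)
            assert compute_D(ho, hy_c) == pytest.approx(c * d_full, abs=1e-12)

    @pytest.mark.parametrize(
        "ho,hy", [([], []), ([0.5, 0.5], [1.0]), ([0.5, 0.6], [0.5, 1.2])]
    )
    def test_invalid_inputs(self, ho, hy):
        with pytest.raises(ValueError):
            compute_D(ho, hy)


class TestCombineDuplicates:
    def _table(self, rows):
        df = snp_frame([r[:3] for r in rows])
        n = max(len(r[3]) for r in rows)
        for j in range(n):
            df[f"h_O_{j + 1}"] = [r[3][j] if j < len(r[3]) else np.nan for r in rows]
            df[f"h_Y_{j + 1}"] = [r[4][j] if j < len(r[4]) else np.nan for r in rows]
        return df

    def test_no_duplicates_passthrough(self):
        df = self._table(
            [
                ("A", 10, "s1", [0.5, 0.5], [0.4, 0.6]),
                ("A", 20, "s2", [0.3, 0.7], [0.2, 0.8]),
            ]
        )
        out = combine_duplicate_snps(df)
        pd.testing.assert_frame_equal(out, df)

    def test_pair_combines_and_renormalizes(self):
        # one position observed with 2 founders in each of two sub-populations:
        # combined record has n = 4 and each group's vector sums to 1
        df = self._table(
            [
                ("A", 10, "s1", [0.5, 0.5], [0.4, 0.6]),
                ("A", 10, "s1b", [0.8, 0.2], [0.9, 0.1]),
            ]
        )
        out = combine_duplicate_snps(df)
        assert len(out) == 1
        out = add_d_scores(out)
        ho = out[[f"h_O_{j}" for j in range(1, 5)]].to_numpy()[0]
        hy = out[[f"h_Y_{j}" for j in range(1, 5)]].to_numpy()[0]
        assert ho.sum() == pytest.approx(1.0, abs=1e-9)
        assert hy.sum() == pytest.approx(1.0, abs=1e-9)
        # concatenation then renormalization: [0.5,0.5,0.8,0.2] / 2
        np.testing.assert_allclose(ho, [0.25, 0.25, 0.4, 0.1])

    def test_three_way_duplicate_single_record(self):
        df = self._table(
            [
                ("A", 10, "a", [0.5, 0.5], [0.5, 0.5]),
                ("A", 10, "b", [0.6, 0.4], [0.4, 0.6]),
                ("A", 10, "c", [0.7, 0.3], [0.3, 0.7]),
                ("B", 5, "d", [1.0, 0.0], [0.0, 1.0]),
            ]
        )
        out = combine_duplicate_snps(df)
        assert len(out) == 2
        merged = out[(out["chrom"] == "A") & (out["pos"] == 10)]
        assert len(merged) == 1
        ho = merged[[c for c in out.columns if c.startswith("h_O_")]].to_numpy(float)
        assert int((~np.isnan(ho)).sum()) == 6

    def test_mixed_n_after_combining(self):
        # duplicate with 2 and 3 founders -> combined n = 5; D uses n = 5
        rows = [
            ("A", 10, "a", [0.5, 0.5], [0.4, 0.6]),
            ("A", 10, "b", [0.2, 0.3, 0.5], [0.3, 0.3, 0.4]),
        ]
        out = add_d_scores(combine_duplicate_snps(self._table(rows)))
        ho = np.concatenate([[0.5, 0.5], [0.2, 0.3, 0.5]])
        hy = np.concatenate([[0.4, 0.6], [0.3, 0.3, 0.4]])
        expected = compute_D(ho / ho.sum(), hy / hy.sum())
        assert out["D"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestSignificance:
    def test_bonferroni_published_constants(self):
        assert bonferroni_threshold(0.05, 1503) == pytest.approx(3.33e-5, rel=5e-3)
        assert bonferroni_threshold(0.05, 11839) == pytest.approx(4.22e-6, rel=5e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    @pytest.mark.parametrize("alpha,m", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_bonferroni_invalid(self, alpha, m):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, m)

    def test_d_cut_is_strict(self):
        df = snp_frame(
            [
                ("A", 1, "at_cut", {"D": 7.9}),
                ("A", 2, "above", {"D": 7.90001}),
                ("A", 3, "paper_example", {"D": 12.009}),
                ("A", 4, "below", {"D": 3.0}),
                ("A", 5, "zero", {"D": 0.0}),
            ]
        )
        out = select_significant(df, SignificancePolicy(mode="d_threshold", d_cut=7.9))
        assert list(out["id"]) == ["above", "paper_example"]

    def test_empty_input(self):
        df = snp_frame([]).reindex(columns=["chrom", "pos", "id", "dataset", "D"])
        out = select_significant(df, SignificancePolicy(mode="d_threshold"))
        assert len(out) == 0

    def test_pvalue_cut_is_strict_and_order_preserved(self):
        cut = 0.05 / 10
        df = snp_frame(
            [
                ("A", 3, "c", {"pvalue": cut * 0.999}),
                ("A", 1, "a", {"pvalue": cut}),
                ("A", 2, "b", {"pvalue": cut * 0.5}),
            ]
        )
        policy = SignificancePolicy(mode="bonferroni", alpha=0.05, m=10)
        out = select_significant(df, policy)
        assert list(out["id"]) == ["c", "b"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = snp_frame(
            [("A", i + 1, f"s{i}", {"D": rng.uniform(0, 20)}) for i in range(50)]
        )
        policy = SignificancePolicy(mode="d_threshold", d_cut=7.9)
        once = select_significant(df, policy)
        twice = select_significant(once, policy)
        pd.testing.assert_frame_equal(once, twice)

    def test_policy_table_mismatch(self):
        df = snp_frame([("A", 1, "s", {"pvalue": 0.01})])
        with pytest.raises(ValueError):
            select_significant(df, SignificancePolicy(mode="d_threshold"))


class TestClassifyCoding:
    @pytest.fixture
    def genes(self):
        # printed 1-based closed gene g1 spans positions 101..200
        return gene_frame(
            [
                ("A", 100, 200, "g1"),
                ("A", 150, 300, "g2"),
                ("B", 0, 50, "g3"),
            ]
        )

    def test_outside_any_gene(self, genes):
        out = classify_coding(snp_frame([("A", 400, "s")]), genes)
        assert not out["coding"].iloc[0]
        assert out["gene_ids"].iloc[0] == ""

    def test_overlapping_genes_both_recorded(self, genes):
        out = classify_coding(snp_frame([("A", 160, "s")]), genes)
        assert out["coding"].iloc[0]
        assert out["gene_ids"].iloc[0] == "g1;g2"

    def test_gene_endpoints_inclusive(self, genes):
        out = classify_coding(
            snp_frame([("A", 101, "at_start"), ("A", 200, "at_end"),
                       ("A", 100, "before"), ("A", 201, "after_in_g2")]),
            genes,
        )
        assert out.set_index("id")["coding"].to_dict() == {
            "at_start": True, "at_end": True, "before": False, "after_in_g2": True
        }

    def test_unknown_chromosome_flagged_noncoding(self, genes, caplog):
        out = classify_coding(snp_frame([("Z", 5, "s")]), genes)
        assert not out["coding"].iloc[0]

    def test_coding_noncoding_partition(self, genes):
        rng = np.random.default_rng(3)
        snps = snp_frame(
            [("A", int(p), f"s{i}") for i, p in enumerate(rng.integers(1, 500, 200))]
        )
        out = classify_coding(snps, genes)
        assert len(out) == len(snps)
        assert ((out["gene_ids"] != "") == out["coding"]).all()


class TestAssignBins:
    def test_bin_arithmetic(self, small_layout):
        snps = snp_frame(
            [("A", 1, "a"), ("A", 80_000, "b"), ("A", 80_001, "c"), ("B", 1, "d")]
        )
        out = assign_bins(snps, small_layout)
        assert list(out["bin"]) == [1, 1, 2, 11]

    def test_every_snp_in_exactly_one_bin(self, small_layout):
        rng = np.random.default_rng(7)
        snps = snp_frame(
            [("A", int(p), f"s{i}") for i, p in enumerate(rng.integers(1, 800_001, 500))]
        )
        out = assign_bins(snps, small_layout)
        occupancy = out.groupby("bin").size()
        assert occupancy.sum() == len(snps)
        assert out["bin"].between(1, 10).all()

    def test_out_of_range_position_raises(self, small_layout):
        with pytest.raises(ValueError, match="A:800001"):
            assign_bins(snp_frame([("A", 800_001, "s")]), small_layout)

    def test_unknown_chromosome_raises(self, small_layout):
        with pytest.raises(ValueError):
            assign_bins(snp_frame([("Z", 1, "s")]), small_layout)
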
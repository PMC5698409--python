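"""Matrix loading, ICE balancing, expected profile and O/E correlation."""

import numpy as np
import pytest

import compartmeth as cm
from compartmeth import CompartmethError
from compartmeth.contact_matrix import (
    expected_by_distance,
    matrix_from_triplets,
    oe_correlation,
    oe_matrix,
)


@pytest.fixture()
def one_chrom_bins():
    return cm.BinTable(cm.Genome(("chr1",), (400_000,)), 40_000)


def naive_alternating_balance(m, max_iter=10_000, tol=1e-12):
    """Independent oracle: alternate row and column normalization of the
    symmetrized scaling until the row sums stop moving."""
    work = m.astype(float).copy()
    for _ in range(max_iter):
        r = work.sum(axis=1)
        r = np.where(r > 0, r / r[r > 0].mean(), 1.0)
        work = work / r[:, None]
        c = work.sum(axis=0)
        c = np.where(c > 0, c / c[c > 0].mean(), 1.0)
        work = work / c[None, :]
        sym = np.sqrt(work * work.T)
        if np.abs(sym.sum(axis=1) - sym.sum(axis=1).mean()).max() < tol:
            work = sym
            break
        work = sym
    return work


class TestLoad:
    def test_triplet_symmetrized(self, one_chrom_bins, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t5\n")
        m = cm.load_matrix(p, one_chrom_bins)
        assert m.matrices["chr1"][0, 1] == 5 and m.matrices["chr1"][1, 0] == 5

    def test_empty_file_all_zero(self, one_chrom_bins, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        m = cm.load_matrix(p, one_chrom_bins)
        assert not m.matrices["chr1"].any()

    def test_diagonal_preserved(self, one_chrom_bins, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t0\t10\n")
        m = cm.load_matrix(p, one_chrom_bins)
        assert m.matrices["chr1"][0, 0] == 10

    def test_out_of_range_and_negative_rejected(self, one_chrom_bins, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t99\t1\n")
        with pytest.raises(CompartmethError, match="out of range"):
            cm.load_matrix(p, one_chrom_bins)
        p.write_text("0\t1\t-2\n")
        with pytest.raises(CompartmethError, match="negative"):
            cm.load_matrix(p, one_chrom_bins)

    def test_inter_chromosomal_triplets_dropped(self, small_bins):
        m = matrix_from_triplets([(0, 1, 3), (0, 12, 7)], small_bins)
        assert m.matrices["chr1"].sum() == 6  # symmetric storage of one pair
        assert not m.matrices["chr2"].any()

    def test_write_read_round_trip(self, one_chrom_bins, tmp_path):
        rng = np.random.default_rng(1)
        raw = rng.poisson(5, (10, 10))
        mat = np.triu(raw) + np.triu(raw, 1).T
        m = cm.ContactMatrix(one_chrom_bins, {"chr1": mat.astype(float)})
        p = tmp_path / "m.tsv"
        cm.write_matrix(m, p)
        back = cm.load_matrix(p, one_chrom_bins)
        assert np.array_equal(back.matrices["chr1"], m.matrices["chr1"])


class TestIceBalance:
    def test_all_ones_already_balanced(self, one_chrom_bins):
        bt = cm.BinTable(cm.Genome(("chr1",), (120_000,)), 40_000)
        m = cm.ContactMatrix(bt, {"chr1": np.ones((3, 3))})
        b = cm.ice_balance(m)
        s = b.matrices["chr1"].sum(axis=1)
        assert np.allclose(s, s.mean())
        assert np.allclose(b.matrices["chr1"] / b.matrices["chr1"][0, 0], np.ones((3, 3)))

    def test_convergence_criterion_met_on_random_matrix(self, one_chrom_bins):
        rng = np.random.default_rng(2)
        raw = rng.uniform(1, 10, (10, 10))
        mat = np.triu(raw) + np.triu(raw, 1).T
        m = cm.ContactMatrix(one_chrom_bins, {"chr1": mat})
        b = cm.ice_balance(m, tol=1e-8, low_coverage_quantile=0.0)
        s = b.matrices["chr1"].sum(axis=1)
        assert np.abs(s / s.mean() - 1).max() <= 1e-8

    def test_zero_row_masked_rest_balanced(self, one_chrom_bins):
        rng = np.random.default_rng(3)
        raw = rng.uniform(1, 10, (10, 10))
        mat = np.triu(raw) + np.triu(raw, 1).T
        mat[4, :] = 0
        mat[:, 4] = 0
        m = cm.ContactMatrix(one_chrom_bins, {"chr1": mat})
        b = cm.ice_balance(m, tol=1e-8, low_coverage_quantile=0.0)
        assert not b.mask["chr1"][4]
        u = b.mask["chr1"]
        s = b.matrices["chr1"].sum(axis=1)[u]
        assert np.abs(s / s.mean() - 1).max() <= 1e-8

    def test_all_zero_matrix_is_error(self, one_chrom_bins):
        m = cm.ContactMatrix(one_chrom_bins, {"chr1": np.zeros((10, 10))})
        with pytest.raises(CompartmethError, match="no usable bins"):
            cm.ice_balance(m)

    def test_zero_pattern_symmetry_and_positive_weights_preserved(
        self, one_chrom_bins
    ):
        rng = np.random.default_rng(4)
        raw = rng.poisson(3, (10, 10)).astype(float)
        mat = np.triu(raw) + np.triu(raw, 1).T
        m = cm.ContactMatrix(one_chrom_bins, {"chr1": mat})
        b = cm.ice_balance(m, low_coverage_quantile=0.0)
        out = b.matrices["chr1"]
        assert np.allclose(out, out.T)
        assert ((mat == 0) == (out == 0)).all()
        w = b.weights["chr1"]
        assert (w[b.mask["chr1"]] > 0).all()

    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_matches_naive_alternating_oracle(self, n):
        rng = np.random.default_rng(n)
        raw = rng.uniform(0.5, 5, (n, n))
        mat = np.triu(raw) + np.triu(raw, 1).T
        bt = cm.BinTable(cm.Genome(("chr1",), (n * 40_000,)), 40_000)
        m = cm.ContactMatrix(bt, {"chr1": mat})
        b = cm.ice_balance(m, max_iter=10_000, tol=1e-12, low_coverage_quantile=0.0)
        oracle = naive_alternating_balance(mat)
        ours = b.matrices["chr1"]
        # both are defined up to overall scale
        assert np.allclose(
            ours / ours.sum(), oracle / oracle.sum(), atol=1e-6
        )


class TestExpectedAndOE:
    def test_constant_off_diagonal_expected(self, one_chrom_bins):
        mat = np.zeros((10, 10))
        for i in range(9):
            mat[i, i + 1] = mat[i + 1, i] = 4.0
        m = cm.ContactMatrix(
            one_chrom_bins, {"chr1": mat}, balanced=True
        )
        e = expected_by_distance(m)
        assert e.values["chr1"][1] == pytest.approx(4.0)

    def test_pure_decay_profile_monotone(self, truth, hic_params):
        import dataclasses

        flat = dataclasses.replace(hic_params, plaid_strength=0.0, tad_boost=0.0)
        raw = cm.generate_contacts(truth, flat, "adult", seed=5)
        b = cm.ice_balance(raw)
        e = expected_by_distance(b)
        vals = e.values["chr1"][1:200]
        # sampling noise dominates at large d; require a strong decreasing
        # trend rather than strict bin-to-bin monotonicity
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.arange(vals.size), vals)
        assert rho < -0.95
        assert (np.diff(vals[:50]) < 0).mean() > 0.9

    def test_single_bin_chromosome_profile(self):
        bt = cm.BinTable(cm.Genome(("chr1",), (40_000,)), 40_000)
        m = cm.ContactMatrix(bt, {"chr1": np.array([[2.0]])}, balanced=True)
        e = expected_by_distance(m)
        assert e.values["chr1"].shape == (1,)

    def test_identical_rows_correlate_perfectly(self):
        bt = cm.BinTable(cm.Genome(("chr1",), (6 * 40_000,)), 40_000)
        rng = np.random.default_rng(6)
        raw = rng.uniform(1, 3, (6, 6))
        mat = np.triu(raw) + np.triu(raw, 1).T
        mat[1] = mat[0]
        mat[:, 1] = mat[:, 0]
        mat[1, 1] = mat[0, 0]
        mat[0, 1] = mat[1, 0] = mat[0, 0]
        m = cm.ContactMatrix(bt, {"chr1": mat}, balanced=True)
        flat_e = cm.ExpectedProfile({"chr1": np.ones(6)})
        corr = oe_correlation(m, flat_e)["chr1"]
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_correlation_entries_bounded_diagonal_one(self, balanced_by_stage):
        b = balanced_by_stage["adult"]
        corr = oe_correlation(b, expected_by_distance(b))["chr1"]
        u = b.mask["chr1"]
        sub = corr[np.ix_(u, u)]
        assert np.nanmax(sub) <= 1 + 1e-9 and np.nanmin(sub) >= -1 - 1e-9
        assert np.allclose(np.diag(sub), 1.0)

    def test_planted_blocks_show_checkerboard(self, truth, balanced_by_stage):
        b = balanced_by_stage["adult"]
        corr = oe_correlation(b, expected_by_distance(b))["chr1"]
        lab = truth.labels["adult"][truth.bin_table.chrom_slice("chr1")]
        sgn = np.where(lab == "A", 1.0, -1.0)
        u = b.mask["chr1"]
        prod = np.outer(sgn[u], sgn[u])
        sub = corr[np.ix_(u, u)]
        off = ~np.eye(sub.shape[0], dtype=bool)
        same_mean = sub[(prod > 0) & off].mean()
        cross_mean = sub[(prod < 0) & off].mean()
        assert same_mean > 0.05 > -0.05 > cross_mean
        assert same_mean - cross_mean > 0.2

    def test_too_few_bins_masked_output(self):
        bt = cm.BinTable(cm.Genome(("chr1",), (2 * 40_000,)), 40_000)
        mat = np.array([[1.0, 2.0], [2.0, 1.0]])
        m = cm.ContactMatrix(bt, {"chr1": mat}, balanced=True)
        corr = oe_correlation(m, expected_by_distance(m))["chr1"]
        assert np.isnan(corr).all()

    def test_oe_of_pure_decay_near_one(self, truth, hic_params):
        import dataclasses

        flat = dataclasses.replace(hic_params, plaid_strength=0.0, tad_boost=0.0)
        raw = cm.generate_contacts(truth, flat, "ES", seed=8)
        b = cm.ice_balance(raw)
        oe = oe_matrix(b, expected_by_distance(b))["chr1"]
        near = np.abs(np.arange(500)[:, None] - np.arange(500)[None, :]) <= 30
        vals = oe[near & np.isfinite(oe)]
        assert abs(np.nanmean(vals) - 1) < 0.05
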
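import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crelink.iofmt import GeneRecord, GenomicInterval
from crelink.linkinfer import (
    LinkMatrix,
    RegulatoryLink,
    link_distance_distribution,
    pairwise_correlation_screen,
    strategy1_links,
    strategy2_links,
    strategy3_links,
    weighted_spearman,
    wilcoxon_rank_sum,
)


def weighted_pearson_on_ranks(x, y, w):
    """Independent brute-force oracle for the weighted rank correlation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    w = np.asarray(w, float)
    mx = np.average(rx, weights=w)
    my = np.average(ry, weights=w)
    cov = np.average((rx - mx) * (ry - my), weights=w)
    return cov / np.sqrt(
        np.average((rx - mx) ** 2, weights=w) * np.average((ry - my) ** 2, weights=w)
    )


class TestWeightedSpearman:
    def test_perfect_monotone_relations(self):
        w = np.ones(5)
        assert weighted_spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], w) == pytest.approx(-1)
        assert weighted_spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], w) == pytest.approx(1)

    def test_equal_weights_match_classic_spearman(self, rng):
        for _ in range(100):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            classic = stats.spearmanr(x, y).statistic
            assert abs(weighted_spearman(x, y, np.ones(30)) - classic) < 1e-12

    def test_hand_case_matches_formula_oracle(self):
        x, y, w = [1, 2, 3, 4], [1, 3, 2, 4], [1, 1, 1, 4]
        assert weighted_spearman(x, y, w) == pytest.approx(
            weighted_pearson_on_ranks(x, y, w), abs=1e-12
        )

    def test_random_weights_match_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = x * 0.5 + rng.normal(size=15)
            w = rng.uniform(0.1, 3.0, size=15)
            assert weighted_spearman(x, y, w) == pytest.approx(
                weighted_pearson_on_ranks(x, y, w), abs=1e-12
            )

    def test_constant_input_returns_nan_with_warning(self, caplog):
        assert np.isnan(weighted_spearman([1, 1, 1], [1, 2, 3], [1, 1, 1]))
        assert "constant" in caplog.text

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_spearman([1, 2, 3], [1, 2, 3], [-1, 1, 1])
        with pytest.raises(ValueError):
            weighted_spearman([1, 2, 3], [1, 2, 3], [0, 0, 0])


class TestWilcoxon:
    def test_exact_hand_value(self):
        # most extreme split of 6 tie-free values: one-sided mass 1/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_exact_path_matches_scipy_exact(self, rng):
        for _ in range(25):
            a = rng.permutation(12)[:5].astype(float)
            b = np.setdiff1d(np.arange(12), a)[:5].astype(float)
            ours = wilcoxon_rank_sum(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_tied_large_sample_close_to_scipy_asymptotic(self, rng):
        a = rng.integers(0, 6, size=30).astype(float)
        b = rng.integers(1, 7, size=40).astype(float)
        ours = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 2], [3, 4, 5])


def _make_gene(gene_id, chrom, tss):
    return GeneRecord(gene_id, GenomicInterval(chrom, tss, tss + 1000, "+"))


class TestStrategy1:
    def test_identical_distal_and_promoter_rows_link(self, rng):
        peaks = [GenomicInterval("chr1", 900, 1100), GenomicInterval("chr1", 50_000, 50_200)]
        genes = [_make_gene("g", "chr1", 1000)]
        signal = rng.uniform(size=20)
        ca = np.vstack([signal, signal])
        H = np.ones((1, 20))
        (link,) = strategy1_links(ca, peaks, genes, H)
        assert link.peak_index == 1 and link.statistic == pytest.approx(1.0)
        assert link.signature_index == 0

    def test_gene_without_nearby_peaks_yields_nothing(self, rng):
        peaks = [GenomicInterval("chr1", 900, 1100)]
        genes = [_make_gene("g", "chr9", 1000)]
        ca = rng.uniform(size=(1, 20))
        assert strategy1_links(ca, peaks, genes, np.ones((1, 20))) == []

    def test_independent_rows_rarely_pass_threshold(self, rng):
        """Monte-Carlo null: random 100-cell rows exceed rho 0.25 rarely."""
        n_hit = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(size=100)
            y = rng.uniform(size=100)
            if weighted_spearman(x, y, np.ones(100)) > 0.25:
                n_hit += 1
        assert n_hit / reps < 0.05


class TestStrategy2:
    def test_proportional_accessibility_and_expression_link(self, rng):
        peaks = [GenomicInterval("chr1", 50_000, 50_200)]
        genes = [_make_gene("g", "chr1", 1000)]
        expr = rng.uniform(1, 5, size=20)
        ge = pd.DataFrame([expr], index=["g"], columns=[f"c{i}" for i in range(20)])
        ca = (2.0 * expr)[None, :]
        (link,) = strategy2_links(ca, ge, peaks, genes, np.ones((1, 20)))
        assert link.statistic == pytest.approx(1.0)

    def test_anticorrelated_pair_not_linked(self, rng):
        peaks = [GenomicInterval("chr1", 50_000, 50_200)]
        genes = [_make_gene("g", "chr1", 1000)]
        expr = rng.uniform(1, 5, size=20)
        ge = pd.DataFrame([expr], index=["g"], columns=[f"c{i}" for i in range(20)])
        ca = (-expr + 10.0)[None, :]
        assert strategy2_links(ca, ge, peaks, genes, np.ones((1, 20))) == []


class TestStrategy3:
    def _fixture(self, rng, shift):
        cells = [f"c{i}" for i in range(100)]
        on = np.zeros(100, dtype=int)
        on[:50] = 1
        expr = rng.normal(10, 1, size=100) + shift * on
        ge = pd.DataFrame([expr], index=["g"], columns=cells)
        peaks = [GenomicInterval("chr1", 50_000, 50_200)]
        genes = [_make_gene("g", "chr1", 1000)]
        mask = on[None, :]
        return ge, mask, peaks, genes

    def test_planted_shift_recovered(self, rng):
        ge, mask, peaks, genes = self._fixture(rng, shift=5.0)
        links, lm = strategy3_links(ge, mask, peaks, genes)
        assert len(links) == 1 and links[0].statistic < 0.05
        assert links[0].n_cells_on == 50
        np.testing.assert_array_equal(lm.matrix[0], mask[0])

    def test_all_on_mask_untested(self, rng):
        ge, _, peaks, genes = self._fixture(rng, shift=5.0)
        links, lm = strategy3_links(ge, np.ones((1, 100), dtype=int), peaks, genes)
        assert links == [] and lm.matrix.shape == (0, 100)

    def test_link_matrix_row_is_mask_row(self, rng):
        ge, mask, peaks, genes = self._fixture(rng, shift=5.0)
        _, lm = strategy3_links(ge, mask, peaks, genes)
        frame = lm.to_frame()
        assert list(frame.columns) == list(ge.columns)

    def test_stored_statistics_respect_thresholds(self, rng):
        """Post-hoc audit: every emitted link satisfies its own cutoff."""
        ge, mask, peaks, genes = self._fixture(rng, shift=2.0)
        links, _ = strategy3_links(ge, mask, peaks, genes, alpha=0.05)
        assert all(l.statistic < 0.05 for l in links)


class TestPairwiseScreen:
    def test_planted_positive_pairs_only(self, rng):
        base = rng.uniform(1, 5, size=(5, 40))
        ge = pd.DataFrame(base + rng.normal(0, 0.01, base.shape),
                          index=[f"g{i}" for i in range(5)])
        ca = base * 3.0
        pairs = [(i, f"g{i}") for i in range(5)]
        counts, table = pairwise_correlation_screen(ca, ge, pairs)
        assert counts["negative"] == 0 and counts["positive"] == 5

    def test_pearson_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        ge = pd.DataFrame([y], index=["g"])
        counts, table = pairwise_correlation_screen(x[None, :], ge, [(0, "g")])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert table["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_null_data_controls_fdr(self, rng):
        ca = rng.normal(size=(200, 50))
        ge = pd.DataFrame(rng.normal(size=(200, 50)),
                          index=[f"g{i}" for i in range(200)])
        pairs = [(i, f"g{i}") for i in range(200)]
        counts, _ = pairwise_correlation_screen(ca, ge, pairs, fdr=0.10)
        n_sig = counts["positive"] + counts["negative"]
        se = np.sqrt(0.10 * 0.90 / 200)
        assert n_sig / 200 <= 0.10 + 2 * se

    def test_constant_vectors_skipped(self, rng):
        ca = np.vstack([np.ones(10), rng.normal(size=10)])
        ge = pd.DataFrame(rng.normal(size=(1, 10)), index=["g"])
        counts, table = pairwise_correlation_screen(ca, ge, [(0, "g"), (1, "g")])
        assert counts["tested"] == 1


class TestDistanceDistribution:
    def test_single_proximal_link(self):
        peaks = [GenomicInterval("chr1", 1400, 1600)]  # midpoint 1500
        genes = [_make_gene("g", "chr1", 1000)]
        hist = link_distance_distribution([RegulatoryLink(0, "g", 3, 0.01)], peaks, genes)
        assert hist[0] == 1 and hist.sum() == 1

    def test_empty_links_error(self):
        with pytest.raises(ValueError):
            link_distance_distribution([], [], [])

    def test_all_beyond_range_error(self):
        peaks = [GenomicInterval("chr1", 5_000_000, 5_000_200)]
        genes = [_make_gene("g", "chr1", 1000)]
        with pytest.raises(ValueError, match="beyond"):
            link_distance_distribution([RegulatoryLink(0, "g", 3, 0.01)], peaks, genes)


class TestLinkMatrixContainer:
    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="binary"):
            LinkMatrix(np.array([[0.5]]), [RegulatoryLink(0, "g", 3, 0.01)], ["c0"])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            LinkMatrix(np.zeros((1, 2)), [RegulatoryLink(0, "g", 3, 0.01)], ["c0"])
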
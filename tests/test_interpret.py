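"""Summary-statistic vector, Pearson correlations, column clustering."""

import numpy as np
import pytest

from discscan import interpret as itp
from discscan import network as nw
from discscan.regions import region_from_01

from conftest import pi_allpairs


def region_from_cols(cols, positions=None, S=36):
    cols = np.asarray(cols)
    if positions is None:
        positions = np.arange(1, cols.shape[1] + 1) * 100
    return region_from_01(cols, positions, S=S)


class TestSummaryStats:
    def test_vector_length_and_decomposition(self, neutral_regions):
        v = itp.compute_summary_stats(neutral_regions[0])
        assert v.shape == (61,)
        assert len(itp.STAT_NAMES) == 61
        assert itp.N_SFS + itp.N_DIST + itp.N_LD + 2 == 61
        assert itp.STAT_NAMES[0] == "sfs_1"
        assert itp.STAT_NAMES[-2:] == ["pi", "n_hap"]

    def test_pi_hand_example(self):
        # 4 haplotypes, 2 sites with minor counts (1, 2):
        # pi = 2*(1/4)(3/4)*(4/3) + 2*(1/2)(1/2)*(4/3) = 0.5 + 2/3 = 7/6
        cols = np.array([
            [1, 1],
            [0, 1],
            [0, 0],
            [0, 0],
        ])
        region = region_from_cols(cols, S=2)
        v = itp.compute_summary_stats(region)
        assert v[itp.STAT_NAMES.index("pi")] == pytest.approx(7 / 6)

    def test_sfs_counts_minor_alleles(self):
        # minor counts: 1, 1, 2, 3 over 8 haplotypes
        rng = np.random.default_rng(0)
        cols = np.zeros((8, 4), dtype=int)
        for j, c in enumerate((1, 1, 2, 3)):
            cols[rng.choice(8, size=c, replace=False), j] = 1
        v = itp.compute_summary_stats(region_from_cols(cols, S=4))
        assert v[0] == 2 and v[1] == 1 and v[2] == 1
        assert v[3:9].sum() == 0

    def test_n_hap_counts_distinct_rows(self):
        cols = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
        ])
        v = itp.compute_summary_stats(region_from_cols(cols, S=3))
        assert v[itp.STAT_NAMES.index("n_hap")] == 3

    def test_n_hap_bounds(self, neutral_regions):
        for r in neutral_regions[:20]:
            nh = itp.compute_summary_stats(r)[itp.STAT_NAMES.index("n_hap")]
            assert 2 <= nh <= r.n_haplotypes

    def test_dist_entries_match_channel(self, neutral_regions):
        r = neutral_regions[0]
        v = itp.compute_summary_stats(r)
        assert np.allclose(v[9:44], r.tensor().values[0, 1:36, 1])

    def test_pi_matches_allpairs_hamming(self, neutral_regions,
                                         sweep_regions):
        idx = itp.STAT_NAMES.index("pi")
        for r in (neutral_regions[:30] + sweep_regions[:20]):
            assert itp.compute_summary_stats(r)[idx] == pytest.approx(
                pi_allpairs(r), abs=1e-10)

    def test_n_hap_matches_row_set(self, neutral_regions):
        idx = itp.STAT_NAMES.index("n_hap")
        for r in neutral_regions[:30]:
            oracle = len({tuple(row) for row in r.genotypes})
            assert itp.compute_summary_stats(r)[idx] == oracle

    def test_all_padding_rejected(self):
        from discscan.regions import HaplotypeRegion

        r = HaplotypeRegion(chrom="c", start=0, end=100,
                            positions=np.array([], dtype=np.int64),
                            genotypes=np.zeros((4, 36), dtype=np.int8),
                            label="simulated-neutral")
        with pytest.raises(ValueError, match="no non-padded"):
            itp.compute_summary_stats(r)

    def test_ld_bins_cover_all_separations(self):
        edges = itp._ld_bin_edges(36)
        assert edges[0] == 1 and edges[-1] == 36
        assert len(edges) == itp.N_LD + 1
        # bins partition separations 1..35
        assert np.all(np.diff(edges) >= 1)


class TestCorrelate:
    def test_copied_statistic_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        stats = rng.random((20, 61))
        hidden = rng.random((20, 128))
        hidden[:, 5] = stats[:, 3]
        cm = itp.correlate(hidden, rng.random(20), stats)
        assert cm.values[3, 5] == pytest.approx(1.0)
        assert cm.values.shape == (61, 129)

    def test_dead_unit_flagged_zero(self):
        rng = np.random.default_rng(2)
        stats = rng.random((10, 61))
        hidden = rng.random((10, 128))
        hidden[:, 7] = 0.0
        cm = itp.correlate(hidden, rng.random(10), stats)
        assert cm.values[:, 7].tolist() == [0.0] * 61
        assert cm.zero_variance_flags[:, 7].all()
        assert not np.isnan(cm.values).any()

    def test_pearson_formula_hand_check(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        stats = np.tile(x[:, None], (1, 61))
        hidden = np.tile(y[:, None], (1, 128))
        cm = itp.correlate(hidden, y, stats)
        r_hand = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert cm.values[0, 0] == pytest.approx(r_hand)

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            itp.correlate(np.zeros((5, 128)), np.zeros(4), np.zeros((5, 61)))

    def test_null_correlation_bound(self, gan_state, neutral_regions):
        """Statistics computed on a permuted region order are uncorrelated
        with the activations: |r| below the 3/sqrt(m) null band."""
        from discscan.regions import stack_tensors

        regions = neutral_regions[:100]
        x = stack_tensors(regions)
        hidden = nw.hidden_activations(gan_state, x)
        prob = nw.predict(gan_state, x)
        stats = itp.summary_stat_matrix(regions)
        rng = np.random.default_rng(3)
        cm_null = itp.correlate(hidden, prob, stats[rng.permutation(100)])
        live = ~cm_null.zero_variance_flags
        vals = np.abs(cm_null.values[live])
        # per-entry null band |r| < 3/sqrt(m); with thousands of (correlated)
        # entries a few heavy-tailed exceedances are expected, so check the
        # band holds for the overwhelming majority and the typical |r| is tiny
        assert (vals < 3 / np.sqrt(100)).mean() > 0.95
        assert np.median(vals) < 1 / np.sqrt(100)


class TestClusterColumns:
    def test_duplicated_columns_adjacent(self):
        rng = np.random.default_rng(4)
        vals = rng.random((61, 129))
        vals[:, 42] = vals[:, 7]
        cm = itp.CorrelationMatrix(
            values=vals, row_names=list(itp.STAT_NAMES),
            zero_variance_flags=np.zeros_like(vals, dtype=bool))
        order = itp.cluster_columns(cm)
        i, j = list(order).index(7), list(order).index(42)
        assert abs(i - j) == 1

    def test_two_block_structure_separates(self):
        rng = np.random.default_rng(5)
        vals = np.zeros((61, 129))
        block = rng.choice(129, size=60, replace=False)
        other = np.setdiff1d(np.arange(129), block)
        vals[:30, block] = 1.0 + 0.01 * rng.random((30, 60))
        vals[30:, other] = -1.0 + 0.01 * rng.random((31, 69))
        cm = itp.CorrelationMatrix(
            values=vals, row_names=list(itp.STAT_NAMES),
            zero_variance_flags=np.zeros_like(vals, dtype=bool))
        order = itp.cluster_columns(cm)
        in_block = np.isin(order, block)
        switches = int(np.abs(np.diff(in_block.astype(int))).sum())
        assert switches == 1  # the two blocks are contiguous in the ordering

    def test_output_is_permutation(self):
        rng = np.random.default_rng(6)
        vals = rng.random((61, 129))
        cm = itp.CorrelationMatrix(
            values=vals, row_names=list(itp.STAT_NAMES),
            zero_variance_flags=np.zeros_like(vals, dtype=bool))
        order = itp.cluster_columns(cm)
        assert sorted(order.tolist()) == list(range(129))


class TestProbabilityReport:
    def test_covers_all_strengths(self, gan_state, tiny_dataset,
                                  neutral_regions):
        by_s = {0.0: neutral_regions[:30]}
        for s in (0.05, 0.1):
            by_s[s] = [r for r in tiny_dataset.regions
                       if r.sel_coeff == s][:30]
        table = itp.probability_correlation_report(gan_state, by_s)
        assert list(table.columns) == ["s=0", "s=0.05", "s=0.1"]
        assert table.shape == (61, 3)
        assert table.abs().max().max() <= 1.0
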
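"""Window encoding, middle-SNP extraction, VCF/mask windowing, archive I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from discscan import regions as rg


class TestEncodeRegion:
    def test_minor_major_coding_hand_example(self):
        # 4 haplotypes x 3 sites, allele-1 counts (1, 2, 3)
        h = np.array([
            [1, 1, 1],
            [0, 1, 1],
            [0, 0, 1],
            [0, 0, 0],
        ])
        out = rg.encode_region(h, [10, 20, 30], S=3)
        expected = np.array([
            [1, 1, -1],    # site 1: carrier minor; site 2: tie -> allele 1
            [-1, 1, -1],   # site 3: allele 1 is major -> -1
            [-1, -1, -1],
            [-1, -1, 1],
        ])
        assert np.array_equal(out.genotypes(), expected)
        assert np.allclose(out.distances(), [0.0, 10 / 50_000, 10 / 50_000])

    def test_exact_s_no_padding(self):
        rng = np.random.default_rng(0)
        h = (rng.random((10, 36)) < 0.4).astype(int)
        h[0] = 1  # ensure segregation with at least one 1 per column
        h[1] = 0
        pos = np.arange(36) * 100 + 5
        out = rg.encode_region(h, pos)
        assert out.values.shape == (10, 36, 2)
        assert not np.any(np.all(out.genotypes() == 0, axis=0))

    def test_zero_padding_short_window(self):
        rng = np.random.default_rng(1)
        h = (rng.random((8, 30)) < 0.5).astype(int)
        h[0], h[1] = 1, 0
        out = rg.encode_region(h, np.arange(30) * 50)
        assert out.values.shape == (8, 36, 2)
        assert np.all(out.values[:, 30:, :] == 0)

    def test_errors(self):
        with pytest.raises(ValueError, match="no segregating sites"):
            rg.encode_region(np.empty((4, 0)), [])
        h = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="increasing"):
            rg.encode_region(h, [20, 10])

    def test_round_trip_idempotent(self):
        """Decoding +1 back to the minor allele and re-encoding is stable."""
        rng = np.random.default_rng(2)
        h = (rng.random((12, 20)) < 0.3).astype(int)
        h[0], h[1] = 1, 0
        pos = np.sort(rng.choice(50_000, size=20, replace=False))
        first = rg.encode_region(h, pos, S=20)
        back = (first.genotypes() == 1).astype(int)
        second = rg.encode_region(back, pos, S=20)
        assert np.array_equal(first.values, second.values)

    def test_distance_channel_sums_below_one_for_50kb(self):
        pos = np.sort(np.random.default_rng(3).choice(
            50_000, size=36, replace=False))
        h = np.tile([[1], [0], [1], [0]], (1, 36))
        out = rg.encode_region(h, pos)
        assert out.distances().sum() <= 1.0


class TestMiddleSnps:
    @pytest.mark.parametrize(
        "k,expected_lo", [(40, 2), (36, 0), (37, 0)],
    )
    def test_floor_convention(self, k, expected_lo):
        h = np.arange(2 * k).reshape(2, k)
        pos = np.arange(k)
        out_h, out_p = rg.middle_snps(h, pos, 36)
        assert np.array_equal(out_p, pos[expected_lo : expected_lo + 36])
        assert np.array_equal(out_h, h[:, expected_lo : expected_lo + 36])

    def test_short_input_returned_unchanged(self):
        h = np.ones((3, 10))
        out_h, out_p = rg.middle_snps(h, np.arange(10), 36)
        assert out_h.shape == (3, 10)


def _write_vcf(path, columns, positions, chrom="1", extra_alt=None,
               unphased_at=None):
    """Write a minimal phased VCF; columns is a list of 0/1 arrays (len 2*n)."""
    n_dip = len(columns[0]) // 2
    samples = "\t".join(f"s{i}" for i in range(n_dip))
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length=1000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}",
    ]
    for j, (col, pos) in enumerate(zip(columns, positions)):
        alt = extra_alt if (extra_alt and j == extra_alt[0]) else "T"
        alt_field = alt[1] if isinstance(alt, tuple) else alt
        sep = "/" if unphased_at == j else "|"
        gts = "\t".join(
            f"{col[2 * i]}{sep}{col[2 * i + 1]}" for i in range(n_dip))
        lines.append(
            f"{chrom}\t{pos + 1}\t.\tC\t{alt_field}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def _write_bed(path, intervals, chrom="1"):
    path.write_text(
        "".join(f"{chrom}\t{s}\t{e}\n" for s, e in intervals))


@pytest.fixture
def toy_vcf_columns():
    rng = np.random.default_rng(7)
    cols = []
    for _ in range(80):
        c = (rng.random(8) < 0.5).astype(int)
        c[0], c[1] = 1, 0  # guarantee segregation
        cols.append(c)
    positions = [100 + 10 * j for j in range(80)]
    return cols, positions


class TestWindowRealData:
    def test_two_windows_from_80_snps(self, tmp_path, toy_vcf_columns):
        cols, pos = toy_vcf_columns
        vcf, bed = tmp_path / "t.vcf", tmp_path / "m.bed"
        _write_vcf(vcf, cols, pos)
        _write_bed(bed, [(0, 10_000)])
        wins = list(rg.window_real_data(str(vcf), str(bed), S=36))
        assert len(wins) == 2  # last 8 SNPs discarded
        assert all(w.n_snps == 36 for w in wins)
        assert wins[0].start == 100 and wins[0].end == 451
        for w in wins:
            g = w.genotypes
            assert np.all((g == 1).sum(axis=0) >= 1)
            assert np.all((g == -1).sum(axis=0) >= 1)

    def test_low_callable_window_dropped(self, tmp_path, toy_vcf_columns):
        cols, pos = toy_vcf_columns
        vcf, bed = tmp_path / "t.vcf", tmp_path / "m.bed"
        _write_vcf(vcf, cols, pos)
        # window 2 spans [460, 812): cover only [460, 600) -> ~40%
        _write_bed(bed, [(0, 451), (460, 600)])
        wins = list(rg.window_real_data(str(vcf), str(bed), S=36))
        assert len(wins) == 1

    def test_triallelic_record_filtered(self, tmp_path, toy_vcf_columns):
        cols, pos = toy_vcf_columns
        vcf, bed = tmp_path / "t.vcf", tmp_path / "m.bed"
        _write_vcf(vcf, cols, pos, extra_alt=(10, "A,G"))
        _write_bed(bed, [(0, 10_000)])
        wins = list(rg.window_real_data(str(vcf), str(bed), S=36))
        assert len(wins) == 2
        # first window is built from the remaining 79 sites
        assert wins[0].positions[10] == pos[11]

    def test_unphased_rejected(self, tmp_path, toy_vcf_columns):
        cols, pos = toy_vcf_columns
        vcf, bed = tmp_path / "t.vcf", tmp_path / "m.bed"
        _write_vcf(vcf, cols, pos, unphased_at=3)
        _write_bed(bed, [(0, 10_000)])
        with pytest.raises(ValueError, match="unphased"):
            list(rg.window_real_data(str(vcf), str(bed), S=36))

    def test_missing_contig_dropped_with_warning(self, tmp_path, caplog,
                                                 toy_vcf_columns):
        cols, pos = toy_vcf_columns
        vcf, bed = tmp_path / "t.vcf", tmp_path / "m.bed"
        _write_vcf(vcf, cols, pos, chrom="2")
        _write_bed(bed, [(0, 10_000)], chrom="1")
        with caplog.at_level("WARNING"):
            wins = list(rg.window_real_data(str(vcf), str(bed), S=36))
        assert wins == []
        assert any("absent from mask" in r.message for r in caplog.records)


class TestMask:
    def test_merge_and_fraction(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("1\t0\t100\n1\t50\t200\n1\t300\t400\n")
        mask = rg.read_bed_mask(str(bed))
        assert mask["1"].tolist() == [[0, 200], [300, 400]]
        assert rg.callable_fraction(mask["1"], 0, 400) == pytest.approx(0.75)


class TestArchive:
    def test_round_trip(self, tmp_path, neutral_regions):
        path = tmp_path / "arch.npz"
        rg.save_regions(str(path), neutral_regions[:5])
        back = rg.load_regions(str(path))
        assert len(back) == 5
        for a, b in zip(neutral_regions[:5], back):
            assert np.array_equal(a.genotypes, b.genotypes)
            assert np.array_equal(a.positions, b.positions)
            assert (a.chrom, a.start, a.end, a.label, a.sel_coeff) == (
                b.chrom, b.start, b.end, b.label, b.sel_coeff)

    def test_mixed_shapes_rejected(self, tmp_path, neutral_regions):
        small = rg.region_from_01(
            np.array([[1, 0], [0, 1]]), [5, 9], S=36)
        with pytest.raises(ValueError, match="share"):
            rg.save_regions(str(tmp_path / "x.npz"),
                            [neutral_regions[0], small])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(3, 12),
    k=st.integers(1, 50),
    seed=st.integers(0, 10_000),
)
def test_encoding_invariants_property(n, k, seed):
    """Every encoded window satisfies the coding invariants."""
    rng = np.random.default_rng(seed)
    h = (rng.random((n, k)) < rng.uniform(0.1, 0.9)).astype(int)
    h[0], h[1] = 1, 0
    pos = np.sort(rng.choice(100_000, size=k, replace=False))
    out = rg.encode_region(h, pos)
    g = out.genotypes()
    nonzero = ~np.all(g == 0, axis=0)
    assert np.all((g[:, nonzero] == 1).any(axis=0))
    assert np.all((g[:, nonzero] == -1).any(axis=0))
    assert np.all((g[:, nonzero] == 1).sum(axis=0) <= n / 2)
    # distance channel in [0,1], identical down rows
    assert np.all(out.values[..., 1] >= 0) and np.all(out.values[..., 1] <= 1)
    assert np.all(out.values[:, :, 1] == out.values[:1, :, 1])
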
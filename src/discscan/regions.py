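"""Haplotype windows and their fixed-shape network encoding.

A genomic window is represented two ways: a :class:`HaplotypeRegion` carrying
the +1/-1/0-coded genotype matrix together with SNP coordinates and provenance,
and a :class:`RegionTensor`, the (n, S, 2) array the discriminator consumes
(channel 0 = genotypes, channel 1 = rescaled inter-SNP distances replicated
down the haplotype rows).

Coding convention: at each segregating site the minor allele is +1 and the
major allele is -1; at an exact 50% tie the ALT (or derived, for simulated
data) allele is +1. Windows with fewer than S SNPs are right-padded with zero
columns in both channels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: fixed rescaling span for the inter-SNP distance channel, in bp.  Both
#: simulated 50 kb regions and real windows (variable bp span) are divided by
#: the same denominator so that SNP density is comparable between them.
DISTANCE_SPAN = 50_000

LABEL_REAL = "real"
LABEL_NEUTRAL = "simulated-neutral"
LABEL_SELECTED = "simulated-selected"
_LABELS = (LABEL_REAL, LABEL_NEUTRAL, LABEL_SELECTED)


@dataclasses.dataclass
class RegionTensor:
    """The (n, S, 2) discriminator input for one window."""

    values: np.ndarray  # float32, shape (n, S, 2)

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def S(self) -> int:
        return self.values.shape[1]

    def genotypes(self) -> np.ndarray:
        return self.values[:, :, 0]

    def distances(self) -> np.ndarray:
        return self.values[0, :, 1]


@dataclasses.dataclass
class HaplotypeRegion:
    """One genomic window: coded genotypes, coordinates and provenance.

    ``genotypes`` is an (n, S) matrix with entries in {-1, +1, 0}; zero
    columns are right-padding only.  ``positions`` holds the bp positions of
    the non-padded SNP columns (0-based, within [start, end)).
    """

    chrom: str
    start: int
    end: int
    positions: np.ndarray
    genotypes: np.ndarray
    label: str
    sel_coeff: float = 0.0
    info: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        if self.label not in _LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def S(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_snps(self) -> int:
        """Number of non-padded SNP columns."""
        return len(self.positions)

    def tensor(self, span_bp: int = DISTANCE_SPAN) -> RegionTensor:
        """Build the two-channel network input for this region."""
        n, S = self.genotypes.shape
        values = np.zeros((n, S, 2), dtype=np.float32)
        values[:, :, 0] = self.genotypes
        k = self.n_snps
        if k > 1:
            gaps = np.diff(self.positions) / span_bp
            values[:, 1:k, 1] = np.clip(gaps, 0.0, 1.0)
        return RegionTensor(values)


def _code_minor_major(haplotypes01: np.ndarray) -> np.ndarray:
    """Map a 0/1 matrix to minor=+1 / major=-1, ties coding allele 1 as +1."""
    h = np.asarray(haplotypes01)
    n = h.shape[0]
    ones = h.sum(axis=0)
    if np.any(ones == 0) or np.any(ones == n):
        raise ValueError("non-segregating column in input")
    coded = np.where(h == 1, 1, -1).astype(np.int8)
    flip = ones > n / 2  # allele 1 is the major allele: flip signs
    coded[:, flip] *= -1
    return coded


def middle_snps(
    haplotypes01: np.ndarray, positions: Sequence[int], S: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the middle ``S`` SNP columns (floor convention on the offset).

    With k columns, returns columns [floor((k-S)/2), floor((k-S)/2)+S).
    If k < S the input is returned unchanged (padding is handled downstream).
    """
    h = np.asarray(haplotypes01)
    pos = np.asarray(positions)
    k = h.shape[1]
    if k < S:
        return h, pos
    lo = (k - S) // 2
    return h[:, lo : lo + S], pos[lo : lo + S]


def encode_region(
    haplotypes01: np.ndarray,
    positions: Sequence[int],
    span_bp: int = DISTANCE_SPAN,
    S: int = 36,
) -> RegionTensor:
    """Encode a 0/1 haplotype matrix into the (n, S, 2) network input.

    Columns must be biallelic and segregating; ``positions`` must be sorted.
    If there are more than S columns the middle S are retained; if fewer, the
    output is right-padded with zero columns in both channels.  Distance
    channel entry j is (positions[j]-positions[j-1]) / ``span_bp`` for j>=1
    (0 at j=0), clipped to [0, 1].
    """
    h = np.asarray(haplotypes01)
    pos = np.asarray(positions, dtype=np.int64)
    if h.ndim != 2 or h.shape[1] == 0 or pos.shape[0] != h.shape[1]:
        raise ValueError("no segregating sites")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    h, pos = middle_snps(h, pos, S)
    coded = _code_minor_major(h)
    n, k = coded.shape
    values = np.zeros((n, S, 2), dtype=np.float32)
    values[:, :k, 0] = coded
    if k > 1:
        values[:, 1:k, 1] = np.clip(np.diff(pos) / span_bp, 0.0, 1.0)
    return RegionTensor(values)


def region_from_01(
    haplotypes01: np.ndarray,
    positions: Sequence[int],
    chrom: str = "sim",
    start: int = 0,
    end: int = DISTANCE_SPAN,
    label: str = LABEL_NEUTRAL,
    sel_coeff: float = 0.0,
    S: int = 36,
    info: dict | None = None,
) -> HaplotypeRegion:
    """Build a :class:`HaplotypeRegion` (middle-S extraction + coding) from 0/1 data."""
    h = np.asarray(haplotypes01)
    pos = np.asarray(positions, dtype=np.int64)
    if h.ndim != 2 or h.shape[1] == 0:
        raise ValueError("no segregating sites")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    h, pos = middle_snps(h, pos, S)
    coded = _code_minor_major(h)
    n, k = coded.shape
    geno = np.zeros((n, S), dtype=np.int8)
    geno[:, :k] = coded
    return HaplotypeRegion(
        chrom=chrom, start=int(start), end=int(end), positions=pos,
        genotypes=geno, label=label, sel_coeff=float(sel_coeff),
        info=info or {},
    )


# ---------------------------------------------------------------------------
# Real-data ingest: VCF + accessibility mask
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WindowRecord:
    chrom: str
    snp_lo: int            # start SNP index into the per-contig SNP list
    snp_hi: int            # end SNP index (exclusive)
    bp_span: int
    callable_fraction: float


@dataclasses.dataclass
class MaskedWindowIndex:
    """Ordered, non-overlapping S-SNP windows with their callable fractions."""

    windows: list[WindowRecord]


def read_bed_mask(path: str) -> dict[str, np.ndarray]:
    """Read a BED accessibility mask into merged per-contig interval arrays."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            raw.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivals in raw.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def callable_fraction(mask: np.ndarray, start: int, end: int) -> float:
    """Fraction of [start, end) covered by the merged mask intervals."""
    if end <= start:
        return 0.0
    lo = np.clip(mask[:, 0], start, end)
    hi = np.clip(mask[:, 1], start, end)
    return float(np.maximum(hi - lo, 0).sum() / (end - start))


def read_recombination_map(path: str):
    """Read a HapMap-format recombination map into an msprime RateMap."""
    import msprime

    return msprime.RateMap.read_hapmap(path)


def _iter_biallelic_phased(variants, contig_filter=None):
    import pysam  # noqa: F401  (VariantFile handles opened by caller)

    for rec in variants:
        if contig_filter is not None and rec.chrom != contig_filter:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            continue  # drop non-biallelic records
        alleles = []
        for sample in rec.samples.values():
            if not sample.phased:
                raise ValueError(
                    f"unphased genotype at {rec.chrom}:{rec.pos} "
                    f"(record {rec.id or '.'})"
                )
            alleles.extend(sample["GT"])
        yield rec.chrom, rec.pos - 1, np.asarray(alleles, dtype=np.int8)


def window_real_data(
    vcf_path: str,
    mask_path: str,
    S: int = 36,
    min_callable: float = 0.5,
) -> Iterator[HaplotypeRegion]:
    """Window a phased VCF into non-overlapping S-SNP regions.

    Non-biallelic records are dropped; consecutive disjoint blocks of S
    biallelic segregating SNPs are emitted; blocks whose bp span has callable
    fraction below ``min_callable`` are dropped, as is a final partial block.
    VCF coordinates (1-based) are converted to 0-based half-open on ingest.
    """
    import pysam

    mask = read_bed_mask(mask_path)
    vcf = pysam.VariantFile(vcf_path)
    buf_cols: list[np.ndarray] = []
    buf_pos: list[int] = []
    cur_chrom: str | None = None

    def flush_blocks() -> Iterator[HaplotypeRegion]:
        while len(buf_pos) >= S:
            cols = buf_cols[:S]
            pos = np.asarray(buf_pos[:S], dtype=np.int64)
            del buf_cols[:S], buf_pos[:S]
            start, end = int(pos[0]), int(pos[-1]) + 1
            if cur_chrom not in mask:
                logger.warning(
                    "contig %s absent from mask; window %d-%d dropped",
                    cur_chrom, start, end,
                )
                continue
            frac = callable_fraction(mask[cur_chrom], start, end)
            if frac < min_callable:
                continue
            h = np.stack(cols, axis=1)
            yield region_from_01(
                h, pos, chrom=cur_chrom, start=start, end=end,
                label=LABEL_REAL, S=S,
            )

    for chrom, pos0, alleles in _iter_biallelic_phased(vcf):
        if chrom != cur_chrom:
            # a trailing partial block at a contig end is dropped
            buf_cols.clear()
            buf_pos.clear()
            cur_chrom = chrom
        n = alleles.shape[0]
        ones = int(alleles.sum())
        if ones == 0 or ones == n:
            continue  # monomorphic in this sample
        buf_cols.append(alleles)
        buf_pos.append(pos0)
        if len(buf_pos) >= S:
            yield from flush_blocks()


def build_window_index(
    vcf_path: str, mask_path: str, S: int = 36, min_callable: float = 0.5
) -> MaskedWindowIndex:
    """Index retained S-SNP windows without materialising genotype matrices."""
    import pysam

    mask = read_bed_mask(mask_path)
    vcf = pysam.VariantFile(vcf_path)
    windows: list[WindowRecord] = []
    per_contig: dict[str, list[int]] = {}
    for chrom, pos0, alleles in _iter_biallelic_phased(vcf):
        n = alleles.shape[0]
        ones = int(alleles.sum())
        if ones == 0 or ones == n:
            continue
        per_contig.setdefault(chrom, []).append(pos0)
    for chrom, poss in per_contig.items():
        for lo in range(0, len(poss) - S + 1, S):
            start, end = poss[lo], poss[lo + S - 1] + 1
            if chrom not in mask:
                continue
            frac = callable_fraction(mask[chrom], start, end)
            if frac >= min_callable:
                windows.append(WindowRecord(chrom, lo, lo + S, end - start, frac))
    return MaskedWindowIndex(windows)


# ---------------------------------------------------------------------------
# Region archive
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_regions(path: str, regions: Sequence[HaplotypeRegion]) -> None:
    """Write regions to a single array-container archive (.npz).

    All regions in one archive must share (n, S); one record per region holds
    the coded genotype matrix, positions, label, sel_coeff and coordinates.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions to save")
    n, S = regions[0].genotypes.shape
    geno = np.zeros((len(regions), n, S), dtype=np.int8)
    pos = np.full((len(regions), S), -1, dtype=np.int64)
    meta = []
    for i, r in enumerate(regions):
        if r.genotypes.shape != (n, S):
            raise ValueError("archive regions must share (n, S)")
        geno[i] = r.genotypes
        pos[i, : r.n_snps] = r.positions
        meta.append(
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "label": r.label, "sel_coeff": r.sel_coeff, "info": r.info}
        )
    np.savez_compressed(
        path, version=_ARCHIVE_VERSION, genotypes=geno, positions=pos,
        meta=json.dumps(meta),
    )


def load_regions(path: str) -> list[HaplotypeRegion]:
    with np.load(path, allow_pickle=False) as npz:
        if int(npz["version"]) != _ARCHIVE_VERSION:
            raise ValueError("region archive version mismatch")
        geno = npz["genotypes"]
        pos = npz["positions"]
        meta = json.loads(str(npz["meta"]))
    out = []
    for i, m in enumerate(meta):
        p = pos[i]
        out.append(
            HaplotypeRegion(
                chrom=m["chrom"], start=m["start"], end=m["end"],
                positions=p[p >= 0], genotypes=geno[i], label=m["label"],
                sel_coeff=m["sel_coeff"], info=m.get("info", {}),
            )
        )
    return out


def stack_tensors(regions: Sequence[HaplotypeRegion]) -> np.ndarray:
    """Stack region tensors into one (N, n, S, 2) float32 batch array."""
    return np.stack([r.tensor().values for r in regions], axis=0)
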
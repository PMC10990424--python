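"""Interpretability: classical summary statistics vs discriminator internals.

Each region is summarised by 61 statistics — the first nine entries of the
folded site frequency spectrum (minor-allele counts 1..9, non-segregating
sites excluded), the 35 rescaled inter-SNP distances, fifteen binned linkage
disequilibrium (LD) statistics, pairwise heterozygosity (pi), and the number
of unique haplotypes across the S SNPs.  These are correlated (Pearson) with
the 128 activations of the last hidden layer plus the final probability, and
the resulting 129 columns are ordered by agglomerative clustering of their
correlation profiles for heatmap display.

The LD statistics are mean r^2 over SNP pairs grouped into 15 bins of
index separation (bin edges chosen to equalize pair counts); r^2 is computed
from haplotype frequencies of the minor alleles.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import network as nw
from .regions import HaplotypeRegion, stack_tensors

N_SFS = 9
N_DIST = 35
N_LD = 15
N_STATS = N_SFS + N_DIST + N_LD + 2  # + pi + n_hap = 61

STAT_NAMES = (
    [f"sfs_{k}" for k in range(1, N_SFS + 1)]
    + [f"dist_{k}" for k in range(1, N_DIST + 1)]
    + [f"ld_{k}" for k in range(1, N_LD + 1)]
    + ["pi", "n_hap"]
)


def _ld_bin_edges(S: int, n_bins: int = N_LD) -> np.ndarray:
    """Bin edges over index separations d = 1..S-1, equalizing pair counts.

    Separation d contributes S-d SNP pairs; edges[i] <= d < edges[i+1]
    defines bin i.
    """
    seps = np.arange(1, S)
    weights = S - seps
    cum = np.cumsum(weights)
    targets = cum[-1] * np.arange(1, n_bins) / n_bins
    cuts = np.searchsorted(cum, targets) + 1  # first separation of next bin
    edges = np.concatenate([[1], np.unique(cuts), [S]])
    return edges


def compute_summary_stats(region: HaplotypeRegion) -> np.ndarray:
    """The 61-entry per-region statistic vector (see module docstring)."""
    geno = np.asarray(region.genotypes)
    n, S = geno.shape
    k = region.n_snps
    if k == 0:
        raise ValueError("region has no non-padded SNP columns")
    g = geno[:, :k]
    minor = (g == 1).sum(axis=0)  # minor allele is coded +1

    sfs = np.zeros(N_SFS)
    for c in minor:
        if 1 <= c <= N_SFS:
            sfs[c - 1] += 1

    dist = np.zeros(N_DIST)
    tensor = region.tensor().values
    d_chan = tensor[0, 1:, 1]
    dist[: min(N_DIST, S - 1)] = d_chan[: N_DIST]

    ld = np.zeros(N_LD)
    if k >= 2:
        edges = _ld_bin_edges(S)
        p = minor / n
        carrier = (g == 1)
        # pairwise joint minor-allele frequencies via one matmul
        pab = (carrier.T.astype(np.float64) @ carrier) / n
        denom = np.outer(p * (1 - p), p * (1 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (pab - np.outer(p, p)) ** 2 / denom
        iu, ju = np.triu_indices(k, 1)
        seps = ju - iu
        vals = r2[iu, ju]
        for b in range(min(N_LD, len(edges) - 1)):
            sel = (seps >= edges[b]) & (seps < edges[b + 1])
            if sel.any():
                ld[b] = float(np.nanmean(vals[sel]))

    phat = minor / n
    pi = float((2 * phat * (1 - phat) * n / (n - 1)).sum())
    n_hap = int(np.unique(geno, axis=0).shape[0])
    return np.concatenate([sfs, dist, ld, [pi, n_hap]])


def summary_stat_matrix(regions: Sequence[HaplotypeRegion]) -> np.ndarray:
    return np.stack([compute_summary_stats(r) for r in regions], axis=0)


@dataclasses.dataclass
class CorrelationMatrix:
    """61 named statistics x (128 hidden units + final probability)."""

    values: np.ndarray          # (61, 129)
    row_names: list[str]
    zero_variance_flags: np.ndarray  # bool, shape (61, 129)
    column_order: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"hidden_{j}" for j in range(self.values.shape[1] - 1)]
        cols.append("final_prob")
        return pd.DataFrame(self.values, index=self.row_names, columns=cols)


def correlate(
    hidden: np.ndarray,
    final_prob: np.ndarray,
    stats: np.ndarray,
    row_names: list[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of each statistic with each hidden unit and the
    final probability, across regions.

    Zero-variance columns (dead ReLU units) or rows give a flagged 0 rather
    than NaN.
    """
    hidden = np.asarray(hidden, dtype=np.float64)
    final_prob = np.asarray(final_prob, dtype=np.float64).reshape(-1, 1)
    stats = np.asarray(stats, dtype=np.float64)
    m = stats.shape[0]
    if m < 3:
        raise ValueError("need at least 3 regions")
    if hidden.shape[0] != m or final_prob.shape[0] != m:
        raise ValueError("misaligned region counts between inputs")
    units = np.concatenate([hidden, final_prob], axis=1)

    def standardize(a):
        mu = a.mean(axis=0)
        sd = a.std(axis=0)
        dead = sd == 0
        sd_safe = np.where(dead, 1.0, sd)
        return (a - mu) / sd_safe, dead

    zs, dead_s = standardize(stats)
    zu, dead_u = standardize(units)
    corr = (zs.T @ zu) / m
    flags = np.logical_or.outer(dead_s, dead_u)
    corr[flags] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationMatrix(
        values=corr,
        row_names=row_names or list(STAT_NAMES),
        zero_variance_flags=flags,
    )


def cluster_columns(cm: CorrelationMatrix) -> np.ndarray:
    """Agglomerative clustering (average linkage, Euclidean distance) of the
    columns by their 61-long correlation profiles; returns the dendrogram
    leaf ordering for heatmap display."""
    cols = cm.values.T  # (129, 61)
    link = hierarchy.linkage(cols, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    cm.column_order = order
    return order


def correlation_with_stats(
    state: nw.DiscriminatorState, regions: Sequence[HaplotypeRegion]
) -> CorrelationMatrix:
    """Compute stats, activations and the full correlation matrix in one go."""
    x = stack_tensors(regions)
    hidden = nw.hidden_activations(state, x)
    prob = nw.predict(state, x)
    stats = summary_stat_matrix(regions)
    return correlate(hidden, prob, stats)


def probability_correlation_report(
    state: nw.DiscriminatorState,
    regions_by_strength: dict[float, Sequence[HaplotypeRegion]],
) -> pd.DataFrame:
    """Correlation of each statistic with the final probability, per selection
    strength (plot-ready bar-chart table: rows = statistics, one column per
    selection coefficient, 0 = neutral)."""
    out = {}
    for s_val, regions in sorted(regions_by_strength.items()):
        x = stack_tensors(list(regions))
        prob = nw.predict(state, x)
        stats = summary_stat_matrix(regions)
        cm = correlate(np.empty((len(prob), 0)), prob, stats)
        out[f"s={s_val:g}"] = cm.values[:, -1]
    return pd.DataFrame(out, index=list(STAT_NAMES))


def plot_heatmap(cm: CorrelationMatrix, path: str) -> None:
    """Render the clustered correlation heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cm.column_order if cm.column_order is not None else cluster_columns(cm)
    fig, ax = plt.subplots(figsize=(14, 10))
    im = ax.imshow(cm.values[:, order], aspect="auto", cmap="RdBu_r",
                   vmin=-0.5, vmax=0.5)
    ax.set_yticks(range(len(cm.row_names)))
    ax.set_yticklabels(cm.row_names, fontsize=4)
    ax.set_xlabel("hidden units (clustered) + final probability")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
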
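"""Validation statistics: ROC/AUC, difference-of-means testing, and a
length-preserving permutation test of scan probabilities against a set of
known selected regions.

The permutation test re-places each truth interval uniformly at random within
the scanned coordinate space, keeping its length, and compares the observed
mean smoothed probability inside the truth regions with the permuted null.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .ensemble import ScanResult


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) and AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, with ties counted half (trapezoidal rule over the tie plateau).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(skm.auc(fpr, tpr))


def mean_diff_test(probs_selected, probs_neutral) -> dict:
    """Two-sided Welch (unequal-variance) t-test for a difference in means.

    Returns the t statistic, p-value and both group means.  Two identical
    zero-variance samples give t=0, p=1; zero variance in both samples with
    different means is degenerate and raises.
    """
    a = np.asarray(probs_selected, dtype=np.float64)
    b = np.asarray(probs_neutral, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p_value": 1.0,
                    "mean_selected": float(a.mean()),
                    "mean_neutral": float(b.mean())}
        raise ValueError("degenerate (zero) variance in both samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p_value": float(p),
            "mean_selected": float(a.mean()), "mean_neutral": float(b.mean())}


@dataclasses.dataclass
class TruthRegionSet:
    """Sorted, merged (chrom, start, end) intervals of known selected regions."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        merged: list[list] = []
        for c, s, e in ivals:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], e)
            else:
                merged.append([c, s, e])
        self.intervals = [(c, int(s), int(e)) for c, s, e in merged]

    @classmethod
    def from_bed(cls, path: str) -> "TruthRegionSet":
        ivals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivals.append((f[0], int(f[1]), int(f[2])))
        return cls(ivals)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s}\t{e}\n")


@dataclasses.dataclass
class PermutationReport:
    observed: float
    null_means: np.ndarray
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    p_normal: float
    n_permutations: int
    degenerate_null: bool = False

    def to_json(self, path: str | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["null_means"] = [float(v) for v in self.null_means]
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _windows_in_intervals(
    scan: ScanResult, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean mask of scan windows overlapping (>= 1 bp) any interval."""
    mask = np.zeros(scan.n_windows, dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c, ivals in by_chrom.items():
        sel = np.flatnonzero(scan.chrom == c)
        if sel.size == 0:
            continue
        starts = scan.start[sel]
        ends = scan.end[sel]
        for s, e in ivals:
            mask[sel[(starts < e) & (ends > s)]] = True
    return mask


def place_intervals(
    spans: dict[str, tuple[int, int]],
    lengths: list[int],
    chroms: list[str],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place each interval uniformly at random within the scanned coordinate
    space, preserving its length.

    Chromosomes are weighted by their available placement span; intervals are
    placed independently and may overlap each other.
    """
    placed = []
    for length in lengths:
        avail = np.array([
            max(spans[c][1] - spans[c][0] - length, 0) + 1
            if spans[c][1] - spans[c][0] >= length else 0
            for c in chroms], dtype=np.float64)
        c = chroms[rng.choice(len(chroms), p=avail / avail.sum())]
        start = int(rng.integers(spans[c][0], spans[c][1] - length + 1))
        placed.append((c, start, start + length))
    return placed


def permutation_test(
    scan: ScanResult,
    truth: TruthRegionSet,
    n_perm: int = 100,
    seed: int | None = None,
) -> PermutationReport:
    """Length-preserving permutation test of scan probabilities vs truth.

    The observed statistic is the mean smoothed probability over windows
    intersecting the truth regions.  Each permutation independently re-places
    every truth interval uniformly at random within the scanned coordinate
    space of a chromosome able to contain it (chromosomes weighted by the
    available placement span); permuted intervals may overlap each other.
    The empirical p-value is (1 + #{null >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    chroms = list(dict.fromkeys(scan.chrom.tolist()))  # preserve order
    spans = {}
    for c in chroms:
        sel = scan.chrom == c
        spans[c] = (int(scan.start[sel].min()), int(scan.end[sel].max()))
    obs_mask = _windows_in_intervals(scan, truth.intervals)
    if not obs_mask.any():
        raise ValueError("no scan window overlaps the truth regions")
    observed = float(scan.smoothed[obs_mask].mean())

    lengths = [e - s for _, s, e in truth.intervals]
    max_span = max(hi - lo for lo, hi in spans.values())
    if max(lengths) > max_span:
        raise ValueError("truth region longer than any scanned chromosome")

    null_means = np.empty(n_perm)
    for k in range(n_perm):
        placed = place_intervals(spans, lengths, chroms, rng)
        mask = _windows_in_intervals(scan, placed)
        null_means[k] = scan.smoothed[mask].mean() if mask.any() else np.nan
    null_means = null_means[~np.isnan(null_means)]
    null_mean = float(null_means.mean())
    null_sd = float(null_means.std(ddof=1)) if null_means.size > 1 else 0.0
    # float-noise floor: a constant scan yields sd at machine epsilon
    degenerate = null_sd <= 1e-9 * max(1.0, abs(null_mean))
    z = 0.0 if degenerate else (observed - null_mean) / null_sd
    p_emp = (1 + int((null_means >= observed).sum())) / (null_means.size + 1)
    p_norm = 1.0 if degenerate else float(sps.norm.sf(z))
    return PermutationReport(
        observed=observed, null_means=null_means, null_mean=null_mean,
        null_sd=null_sd, z=float(z), p_empirical=float(p_emp),
        p_normal=p_norm, n_permutations=int(null_means.size),
        degenerate_null=degenerate,
    )
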
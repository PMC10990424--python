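"""Fine-tuning of trained discriminators and smoothed ensemble genome scans.

Fine-tuning re-trains a discriminator on labeled simulations (0 = neutral,
1 = selected) for a short fixed schedule — 2,000 mini-batches of 50 drawn
from the 80% train split — so that high output probabilities can be read as
evidence for the targeted mode of selection.  A genome scan then averages the
predictions of all successfully trained discriminators per non-overlapping
S-SNP window, smooths each window's value with its two upstream and two
downstream neighbours (never across chromosome boundaries), and reports
maximal runs of windows whose smoothed probability exceeds a threshold as
candidate regions.  The default threshold 0.75 is illustrative, not
calibrated: the outputs are not posterior probabilities.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import network as nw
from .regions import HaplotypeRegion, stack_tensors
from .selection import FineTuneDataset

logger = logging.getLogger(__name__)

FINETUNE_BATCHES = 2_000
FINETUNE_BATCH_SIZE = 50
DEFAULT_THRESHOLD = 0.75
SMOOTH_WINDOW = 5  # the window itself plus two neighbours on each side


def fine_tune(
    state: nw.DiscriminatorState,
    ds: FineTuneDataset,
    seed: int | None = None,
    n_batches: int = FINETUNE_BATCHES,
    batch_size: int = FINETUNE_BATCH_SIZE,
    lr: float = 1e-3,
    eval_every: int = 100,
) -> nw.DiscriminatorState:
    """Fine-tune a discriminator on a labeled dataset; returns a new state.

    A degenerate input discriminator is refused: fine-tuning cannot rescue a
    network that ignores its input.  Validation-split loss and accuracy are
    recorded every ``eval_every`` mini-batches into the returned state's
    provenance.
    """
    x_train, y_train = ds.subset_tensors(ds.train_idx)
    x_val, y_val = ds.subset_tensors(ds.val_idx)
    probe = x_train[: min(100, x_train.shape[0])]
    if probe.shape[0] >= 2 and nw.is_degenerate(state, probe):
        raise ValueError(
            "refusing to fine-tune a degenerate discriminator "
            "(constant output on probe regions)")
    out = state.copy()
    rng = np.random.default_rng(seed)
    opt = nw.AdamState(lr=lr)
    history = []
    for b in range(n_batches):
        idx = rng.choice(x_train.shape[0],
                         size=min(batch_size, x_train.shape[0]),
                         replace=x_train.shape[0] < batch_size)
        loss = nw.train_step(out, x_train[idx], y_train[idx], opt, rng)
        if eval_every and (b + 1) % eval_every == 0:
            pv = nw.predict(out, x_val)
            history.append({
                "batch": b + 1,
                "train_loss": loss,
                "val_loss": nw.bce_loss(pv, y_val),
                "val_accuracy": float(((pv > 0.5) == (y_val > 0.5)).mean()),
            })
    out.provenance["fine_tuned"] = ds.scenario
    out.provenance["finetune_history"] = history
    return out


@dataclasses.dataclass
class ScanResult:
    """Per-window ensemble predictions over an ordered window sequence."""

    chrom: np.ndarray       # str per window
    start: np.ndarray
    end: np.ndarray
    raw: np.ndarray         # ensemble mean probability per window
    smoothed: np.ndarray
    per_discriminator: np.ndarray  # (K, n_windows) raw probabilities

    @property
    def n_windows(self) -> int:
        return self.raw.shape[0]

    def write_tsv(self, path: str, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("chrom\tstart\tend\traw\tsmoothed\n")
            for i in range(self.n_windows):
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"{self.raw[i]:.6f}\t{self.smoothed[i]:.6f}\n")


@dataclasses.dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    peak: float
    member_windows: list[int]


def smooth(probs: np.ndarray, chrom: np.ndarray | None = None,
           width: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average over ``width`` windows, truncated at edges.

    With per-window chromosome labels, smoothing never crosses a chromosome
    boundary.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if chrom is not None:
        chrom = np.asarray(chrom)
        out = np.empty_like(probs)
        for c in np.unique(chrom):
            sel = chrom == c
            out[sel] = smooth(probs[sel], None, width)
        return out
    half = width // 2
    n = probs.shape[0]
    csum = np.concatenate([[0.0], np.cumsum(probs)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def scan(
    states: list[nw.DiscriminatorState],
    windows: list[HaplotypeRegion],
    batch_size: int = 256,
) -> ScanResult:
    """Ensemble scan: average per-window predictions over discriminators.

    Windows must be ordered along the genome (grouped by chromosome); all
    discriminators must share the spec's S.
    """
    if not states:
        raise ValueError("empty discriminator list")
    S = states[0].spec.S
    if any(st.spec.S != S for st in states):
        raise ValueError("all discriminators must share S")
    x = stack_tensors(windows)
    per_disc = np.empty((len(states), x.shape[0]))
    for k, st in enumerate(states):
        preds = [
            nw.predict(st, x[i : i + batch_size])
            for i in range(0, x.shape[0], batch_size)
        ]
        per_disc[k] = np.concatenate(preds)
    raw = per_disc.mean(axis=0)
    chrom = np.asarray([w.chrom for w in windows])
    return ScanResult(
        chrom=chrom,
        start=np.asarray([w.start for w in windows]),
        end=np.asarray([w.end for w in windows]),
        raw=raw,
        smoothed=smooth(raw, chrom),
        per_discriminator=per_disc,
    )


def call_candidates(
    result: ScanResult, threshold: float = DEFAULT_THRESHOLD
) -> list[CandidateRegion]:
    """Maximal runs of consecutive windows with smoothed probability above
    the threshold, merged into candidate regions."""
    out: list[CandidateRegion] = []
    above = result.smoothed > threshold
    i = 0
    n = result.n_windows
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and result.chrom[j + 1] == result.chrom[i]:
            j += 1
        members = list(range(i, j + 1))
        out.append(CandidateRegion(
            chrom=str(result.chrom[i]),
            start=int(result.start[i]),
            end=int(result.end[j]),
            peak=float(result.smoothed[i : j + 1].max()),
            member_windows=members,
        ))
        i = j + 1
    return out


def genome_fraction_above(
    result: ScanResult, thresholds: np.ndarray
) -> np.ndarray:
    """(threshold, fraction of windows with smoothed probability above it).

    The curve is a monotone non-increasing step function of the threshold.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    frac = np.array([
        (result.smoothed > t).mean() for t in thresholds])
    return np.column_stack([thresholds, frac])


def write_candidates_bed(
    candidates: list[CandidateRegion], path: str,
    header_lines: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.peak:.4f}\n")
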
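"""Workflow orchestration: seed fan-out, toy fixtures, and the full pipeline.

The pipeline mirrors the intended use of the method: several independent
adversarial training runs on a training population produce a collection of
discriminators; degenerate ones (constant output) are discarded; survivors
are fine-tuned with selection simulations under their own fitted parameters;
and a held-out population's windows are scanned with the ensemble.

All stage seeds fan out deterministically from one master seed via a
counter-based derivation, so any stage can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import zlib

import numpy as np

from . import demography as dg
from . import ensemble as ens
from . import interpret as itp
from . import network as nw
from . import selection as sl
from . import stats as vst
from . import training as tr
from .regions import (
    LABEL_NEUTRAL,
    LABEL_SELECTED,
    HaplotypeRegion,
    load_regions,
    save_regions,
    stack_tensors,
)

logger = logging.getLogger(__name__)

TOY_CHROM = "toy1"


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    tag = zlib.crc32(f"{stage}:{index}".encode())
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclasses.dataclass
class RunConfig:
    """Full configuration of one workflow run (serializable, logged with
    every output)."""

    population: str = "CEU"
    master_seed: int = 0
    n_haplotypes: int = 64
    n_gan_runs: int = 3
    sa: tr.SAConfig = dataclasses.field(default_factory=tr.SAConfig)
    scenario: str = sl.SCENARIO_POSITIVE
    dataset_counts: dict | None = None
    rescale_Q: float = 1.0
    finetune_batches: int = ens.FINETUNE_BATCHES
    threshold: float = ens.DEFAULT_THRESHOLD
    n_permutations: int = 100
    train_regions_path: str | None = None
    scan_regions_path: str | None = None
    truth_bed_path: str | None = None
    out_dir: str | None = None
    allow_same_pop: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return config_hash(self.to_dict())


def make_toy_dataset(
    master_seed: int,
    out_dir: str | None = None,
    n_windows: int = 500,
    n_haplotypes: int = 64,
    frac_selected: float = 0.05,
    params: dg.DemographyParams | None = None,
    sel_coeffs: tuple[float, ...] = (0.05, 0.1),
    L: int = dg.DEFAULT_L,
) -> tuple[list[HaplotypeRegion], vst.TruthRegionSet, dict]:
    """Generate a miniature genome with planted sweeps at known locations.

    Window i occupies [i*L, (i+1)*L) on one toy chromosome; about
    ``frac_selected`` of windows are hard sweeps (s drawn from
    ``sel_coeffs``), the rest neutral under the fitted demography.  The truth
    interval set exactly covers the planted windows.  Deterministic given the
    master seed.
    """
    if params is None:
        params = dg.FITTED_PARAMS["CEU"]
    cfg = dg.SimConfig(n=n_haplotypes, L=L)
    rng = np.random.default_rng(stage_seed(master_seed, "toy-layout"))
    n_sel = max(1, int(round(frac_selected * n_windows)))
    sel_windows = np.sort(rng.choice(n_windows, size=n_sel, replace=False))
    sel_s = rng.choice(sel_coeffs, size=n_sel)

    regions: list[HaplotypeRegion] = []
    truth = []
    j = 0
    for i in range(n_windows):
        seed_i = stage_seed(master_seed, "toy-window", i)
        if j < n_sel and i == sel_windows[j]:
            sel = sl.SelectionConfig(scenario=sl.SCENARIO_POSITIVE,
                                     s=float(sel_s[j]))
            region = sl.simulate_sweep_region(params, sel, cfg, seed=seed_i)
            truth.append((TOY_CHROM, i * L, (i + 1) * L))
            j += 1
        else:
            region = dg.simulate_neutral_region(params, cfg, seed=seed_i)
        region.chrom = TOY_CHROM
        region.positions = region.positions + i * L
        region.start = i * L
        region.end = (i + 1) * L
        regions.append(region)

    truth_set = vst.TruthRegionSet(truth)
    config = {
        "master_seed": master_seed, "n_windows": n_windows,
        "n_haplotypes": n_haplotypes, "frac_selected": frac_selected,
        "sel_coeffs": list(sel_coeffs), "L": L,
        "params": dataclasses.asdict(params),
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        save_regions(os.path.join(out_dir, "toy_regions.npz"), regions)
        truth_set.to_bed(os.path.join(out_dir, "toy_truth.bed"))
        with open(os.path.join(out_dir, "toy_config.json"), "w") as fh:
            json.dump(config, fh, indent=2)
    return regions, truth_set, config


def _probe_batch(ranges: dg.ParamRanges, cfg: dg.SimConfig, seed: int,
                 n_probe: int = 50) -> np.ndarray:
    """Neutral probe regions at distinct parameter draws, for degeneracy checks."""
    rng = np.random.default_rng(seed)
    regions = []
    for _ in range(n_probe):
        p = ranges.sample(rng)
        regions.append(dg.simulate_neutral_region(
            p, cfg, seed=int(rng.integers(2**31 - 1))))
    return stack_tensors(regions)


def run_workflow(
    config: RunConfig,
    train_regions: list[HaplotypeRegion] | None = None,
    scan_regions: list[HaplotypeRegion] | None = None,
    truth: vst.TruthRegionSet | None = None,
    ranges: dg.ParamRanges | None = None,
) -> dict:
    """Execute the full pipeline; returns a dict of in-memory artifacts.

    Train/test separation is enforced: scanning the same archive used for
    adversarial training requires ``allow_same_pop``.
    """
    t_start = time.time()
    if train_regions is None:
        if config.train_regions_path is None:
            raise ValueError("no training regions provided")
        train_regions = load_regions(config.train_regions_path)
    if scan_regions is None:
        if config.scan_regions_path is None:
            raise ValueError("no scan regions provided")
        if (config.scan_regions_path == config.train_regions_path
                and not config.allow_same_pop):
            raise ValueError(
                "scan regions are the GAN training archive; pass "
                "allow_same_pop to override the train/test separation")
        scan_regions = load_regions(config.scan_regions_path)
    elif train_regions is scan_regions and not config.allow_same_pop:
        raise ValueError(
            "scan regions are the GAN training archive; pass allow_same_pop "
            "to override the train/test separation")
    if truth is None and config.truth_bed_path is not None:
        truth = vst.TruthRegionSet.from_bed(config.truth_bed_path)
    if ranges is None:
        ranges = dg.ParamRanges()

    n = train_regions[0].n_haplotypes
    cfg = dg.SimConfig(n=n)
    chash = config.hash()
    header = [f"config_hash={chash}"]

    # stage 1: independent adversarial runs
    runs = []
    for k in range(config.n_gan_runs):
        sa = dataclasses.replace(
            config.sa, seed=stage_seed(config.master_seed, "gan", k))
        t0 = time.time()
        state, params, trace = tr.train_gan(
            train_regions, ranges, cfg, sa, rescale_Q=config.rescale_Q)
        logger.info("stage=gan run=%d seed=%d wall=%.1fs iters=%d",
                    k, sa.seed, time.time() - t0, len(trace))
        runs.append((state, params, trace))

    # stage 2: evaluation — discard degenerate discriminators
    probe = _probe_batch(ranges, cfg,
                         stage_seed(config.master_seed, "probe"))
    survivors = []
    diagnostics = []
    for k, (state, params, trace) in enumerate(runs):
        degenerate = nw.is_degenerate(state, probe)
        diagnostics.append({"run": k, "degenerate": degenerate,
                            "params": dataclasses.asdict(params)})
        if not degenerate:
            survivors.append((k, state, params))
        else:
            logger.warning("stage=eval run=%d discarded (degenerate)", k)
    if not survivors:
        raise RuntimeError(
            "no discriminator survived the degeneracy check; per-run "
            f"diagnostics: {json.dumps(diagnostics)}")

    # stage 3: fine-tune survivors with selection simulations under their
    # own fitted parameters
    tuned = []
    for k, state, params in survivors:
        ds = sl.build_finetune_dataset(
            params, cfg, scenario=config.scenario,
            counts=config.dataset_counts,
            seed=stage_seed(config.master_seed, "dataset", k),
            rescale_Q=config.rescale_Q)
        t0 = time.time()
        tuned.append(ens.fine_tune(
            state, ds, seed=stage_seed(config.master_seed, "finetune", k),
            n_batches=config.finetune_batches))
        logger.info("stage=finetune run=%d wall=%.1fs", k, time.time() - t0)

    # stage 4: ensemble scan of the held-out windows
    result = ens.scan(tuned, scan_regions)
    candidates = ens.call_candidates(result, threshold=config.threshold)

    artifacts = {
        "config_hash": chash,
        "discriminators": tuned,
        "diagnostics": diagnostics,
        "scan": result,
        "candidates": candidates,
    }

    # stage 5: validation and interpretability
    if truth is not None:
        artifacts["permutation"] = vst.permutation_test(
            result, truth, n_perm=config.n_permutations,
            seed=stage_seed(config.master_seed, "permutation"))
    cm = itp.correlation_with_stats(tuned[0], scan_regions)
    itp.cluster_columns(cm)
    artifacts["correlations"] = cm

    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        result.write_tsv(os.path.join(config.out_dir, "scan.tsv"), header)
        ens.write_candidates_bed(
            candidates, os.path.join(config.out_dir, "candidates.bed"), header)
        for i, st in enumerate(tuned):
            nw.save_discriminator(st, os.path.join(
                config.out_dir, f"{config.population}_seed{i}.disc.npz"))
        if "permutation" in artifacts:
            artifacts["permutation"].to_json(
                os.path.join(config.out_dir, "permutation.json"))
        cm.to_frame().to_csv(
            os.path.join(config.out_dir, "correlations.tsv"), sep="\t")
        with open(os.path.join(config.out_dir, "config.json"), "w") as fh:
            json.dump({"hash": chash, **config.to_dict()}, fh, indent=2,
                      default=str)
    logger.info("workflow complete wall=%.1fs", time.time() - t_start)
    return artifacts
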
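"""Adversarial training: simulated annealing over demographic parameters
against gradient updates of the discriminator.

The generator is the explicit coalescent model of :mod:`discscan.demography`,
so it cannot be trained by backpropagation; instead each iteration proposes
parameter updates with a temperature-controlled symmetric kernel and accepts
them by a simulated-annealing rule on the generator objective — the mean
probability the current discriminator assigns to regions simulated under the
candidate parameters (higher = more realistic).  Between proposals the
discriminator takes gradient steps on fresh real (label 1) vs simulated
(label 0) batches under the incumbent parameters.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import demography as dg
from . import network as nw
from .regions import HaplotypeRegion, stack_tensors

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SAConfig:
    """Simulated-annealing schedule and per-iteration batch structure."""

    iterations: int = 300
    proposals_per_iter: int = 1
    batch_size: int = 50
    disc_updates_per_iter: int = 5
    initial_temperature: float = 1.0
    #: SA proposal kernel width as a fraction of each parameter's range
    proposal_width: float = 0.1
    #: final fraction of the schedule run greedily (accept improvements only)
    freeze_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.iterations + 1, self.proposals_per_iter, self.batch_size,
               self.disc_updates_per_iter) <= 0:
            raise ValueError("SAConfig fields must be positive")
        if not 0 <= self.initial_temperature <= 1:
            raise ValueError("temperature must lie in [0, 1]")

    def temperature(self, iteration: int) -> float:
        """Linear cooling from the initial temperature to 0."""
        if self.iterations == 0:
            return 0.0
        return self.initial_temperature * (1 - iteration / self.iterations)


@dataclasses.dataclass
class TraceRecord:
    iteration: int
    params: dg.DemographyParams
    objective: float
    disc_loss: float
    accepted: bool
    temperature: float
    delta: float = 0.0  # candidate objective minus incumbent objective


@dataclasses.dataclass
class TrainTrace:
    records: list[TraceRecord] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> list[dict]:
        return [
            {
                "iteration": r.iteration,
                **{k: getattr(r.params, k) for k in ("N1", "N2", "g", "T1", "T2")},
                "objective": r.objective,
                "disc_loss": r.disc_loss,
                "accepted": int(r.accepted),
                "temperature": r.temperature,
            }
            for r in self.records
        ]

    def write_tsv(self, path: str, header_lines: list[str] | None = None) -> None:
        rows = self.to_rows()
        cols = list(rows[0]) if rows else [
            "iteration", "N1", "N2", "g", "T1", "T2", "objective",
            "disc_loss", "accepted", "temperature"]
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _simulate_batch(
    params: dg.DemographyParams,
    cfg: dg.SimConfig,
    batch_size: int,
    rng: np.random.Generator,
    rescale_Q: float = 1.0,
) -> np.ndarray | None:
    """Simulate a batch of neutral regions; None if the point is invalid."""
    regions = []
    for _ in range(batch_size):
        try:
            regions.append(
                dg.simulate_neutral_region(
                    params, cfg, seed=int(rng.integers(2**31 - 1)),
                    rescale_Q=rescale_Q)
            )
        except RuntimeError:
            return None
    return stack_tensors(regions)


def _sample_real_batch(
    real: np.ndarray, batch_size: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.choice(real.shape[0], size=min(batch_size, real.shape[0]),
                     replace=real.shape[0] < batch_size)
    return real[idx]


def _objective(state: nw.DiscriminatorState, fakes: np.ndarray | None) -> float:
    """Mean discriminator 'real' probability on candidate fakes; invalid
    parameter points score as maximally fake."""
    if fakes is None:
        return 0.0
    return float(nw.predict(state, fakes).mean())


def train_gan(
    real_regions: list[HaplotypeRegion] | np.ndarray,
    ranges: dg.ParamRanges,
    cfg: dg.SimConfig,
    sa: SAConfig,
    initial_params: dg.DemographyParams | None = None,
    initial_state: nw.DiscriminatorState | None = None,
    spec: nw.DiscriminatorSpec | None = None,
    lr: float = 1e-3,
    rescale_Q: float = 1.0,
    free_params: tuple[str, ...] = ("N1", "N2", "g", "T1", "T2"),
) -> tuple[nw.DiscriminatorState, dg.DemographyParams, TrainTrace]:
    """Run the adversarial loop; returns (discriminator, params, trace).

    With ``sa.iterations == 0`` the initial parameters and an untrained
    (randomly initialized) discriminator are returned with an empty trace.
    Passing ``initial_state`` continues training an existing discriminator;
    an empty ``free_params`` tuple freezes the generator (discriminator-only
    updates).
    """
    if isinstance(real_regions, np.ndarray):
        real = real_regions
    else:
        real = stack_tensors(list(real_regions))
    if real.shape[0] == 0:
        raise ValueError("need at least one batch of real regions")
    rng = np.random.default_rng(sa.seed)
    if initial_state is not None:
        state = initial_state.copy()
        int(rng.integers(2**31 - 1))  # keep the seed stream aligned
    else:
        if spec is None:
            spec = nw.DiscriminatorSpec(S=cfg.S)
        state = nw.build_discriminator(spec, seed=int(rng.integers(2**31 - 1)))
    state.provenance["gan_trained"] = True
    state.provenance["training_seed"] = sa.seed

    params = initial_params if initial_params is not None else ranges.sample(rng)
    params = ranges.clip(params)
    opt = nw.AdamState(lr=lr)
    trace = TrainTrace()

    incumbent_fakes = _simulate_batch(params, cfg, sa.batch_size, rng,
                                      rescale_Q)
    retry = 0
    while incumbent_fakes is None:
        retry += 1
        if retry > 10:
            raise RuntimeError(
                "all initial parameter points invalid (no segregating sites)")
        params = ranges.clip(ranges.sample(rng))
        incumbent_fakes = _simulate_batch(params, cfg, sa.batch_size, rng,
                                          rescale_Q)

    for it in range(sa.iterations):
        temp = sa.temperature(it)
        incumbent_obj = _objective(state, incumbent_fakes)

        best_cand, best_obj, best_fakes = None, -math.inf, None
        for _ in range(sa.proposals_per_iter):
            cand = dg.propose_params(params, ranges, temp, rng=rng,
                                     free_params=free_params,
                                     width_frac=sa.proposal_width)
            fakes = _simulate_batch(cand, cfg, sa.batch_size, rng, rescale_Q)
            obj = _objective(state, fakes)
            if obj > best_obj:
                best_cand, best_obj, best_fakes = cand, obj, fakes

        delta = best_obj - incumbent_obj
        frozen = it >= sa.iterations * (1 - sa.freeze_fraction)
        accept = delta > 0 or (
            not frozen and temp > 1e-9
            and rng.random() < math.exp(delta / temp))
        if accept and best_fakes is not None:
            params = best_cand
            incumbent_fakes = best_fakes

        loss = math.nan
        for _ in range(sa.disc_updates_per_iter):
            fakes = _simulate_batch(params, cfg, sa.batch_size, rng, rescale_Q)
            if fakes is None:
                continue
            real_batch = _sample_real_batch(real, sa.batch_size, rng)
            loss = nw.train_step_real_fake(state, real_batch, fakes, opt, rng)
            incumbent_fakes = fakes  # freshest sample under the incumbent
        trace.records.append(TraceRecord(
            iteration=it, params=params,
            objective=best_obj if accept else incumbent_obj,
            disc_loss=loss, accepted=bool(accept), temperature=temp,
            delta=float(delta)))
        if (it + 1) % 50 == 0:
            logger.info("SA iter %d/%d obj=%.3f loss=%.3f", it + 1,
                        sa.iterations, trace.records[-1].objective, loss)

    return state, params, trace


def evaluate_discriminator(
    state: nw.DiscriminatorState,
    real: list[HaplotypeRegion] | np.ndarray,
    fake: list[HaplotypeRegion] | np.ndarray,
    degenerate_tolerance: float = 1e-4,
) -> dict:
    """Accuracy at threshold 0.5 plus mean probabilities and degeneracy flag."""
    if len(real) == 0 or len(fake) == 0:
        raise ValueError("both region sets must be non-empty")
    xr = real if isinstance(real, np.ndarray) else stack_tensors(list(real))
    xf = fake if isinstance(fake, np.ndarray) else stack_tensors(list(fake))
    pr = nw.predict(state, xr)
    pf = nw.predict(state, xf)
    acc = 0.5 * ((pr > 0.5).mean() + (pf <= 0.5).mean())
    probe = np.concatenate([xr, xf], axis=0)
    return {
        "accuracy": float(acc),
        "mean_prob_real": float(pr.mean()),
        "mean_prob_fake": float(pf.mean()),
        "degenerate": nw.is_degenerate(state, probe,
                                       tolerance=degenerate_tolerance),
    }
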
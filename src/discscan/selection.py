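"""Non-neutral training regions: sweeps, balancing selection, introgression.

Each scenario couples two stages:

1. A forward Wright-Fisher simulation of the selected-allele frequency at the
   focal site: diploid binomial sampling each generation with genotype
   fitnesses (1, 1+h*s, 1+s) under the (possibly rescaled) demography.  The
   beneficial mutation enters as a single copy ``t_onset`` generations before
   present (or at the admixture pulse, for introgression).  If the allele is
   lost in any generation, the population state is restored to the previous
   generation and that generation is re-drawn with fresh randomness; a global
   restart cap guards against parameter regimes where the sweep cannot be
   conditioned.

2. A structured coalescent for the sampled haplotypes, conditioned on that
   trajectory: carriers and non-carriers of the selected allele form two
   backgrounds with time-varying sizes N(t)x(t) and N(t)(1-x(t)), and
   lineages swap backgrounds by recombination at an effective per-generation
   rate r*d_eff*(freq of the other background), with d_eff the mean distance
   of a window site from the selected site (L/4).  History deeper than the
   onset of selection is completed by the neutral coalescent under the same
   demography (the recapitation contract), and neutral mutations are overlaid
   at rate mu.  The selected (or introgressed marker) allele itself is added
   as a derived variant at the centre of the region when it segregates in the
   sample.

Population-size rescaling by a factor Q uses N/Q, s*Q, mu*Q, r*Q and t/Q
generations, which leaves the neutral scaled process invariant.
"""

from __future__ import annotations

import dataclasses
import logging

import msprime
import numpy as np

from .demography import DemographyParams, SimConfig, _ts_to_region
from .regions import LABEL_SELECTED, HaplotypeRegion
from . import demography as _demog

logger = logging.getLogger(__name__)

SCENARIO_POSITIVE = "positive"
SCENARIO_BALANCING = "balancing"
SCENARIO_INTROGRESSION = "adaptive_introgression"

#: selection coefficients used for the standard fine-tuning dataset
DATASET_SEL_COEFFS = (0.01, 0.025, 0.05, 0.1)
DATASET_N_PER_COEFF = 600
DATASET_N_NEUTRAL = 3_000
VALIDATION_FRACTION = 0.20

#: effective recombination distance between a window site and the selected
#: site at the centre of the L bp region (mean over the window).
_D_EFF_FRACTION = 0.25

#: floor for structured-coalescent deme sizes (diploids); a background at
#: this size coalesces essentially instantly.
_MIN_DEME_SIZE = 0.25


@dataclasses.dataclass
class SelectionConfig:
    """Settings for one non-neutral scenario.

    ``h`` defaults to genic selection (0.5) for sweeps and to heterozygote
    advantage (2.0) for balancing selection.  ``t_onset`` is the time the
    beneficial mutation is introduced, in generations before present.  The
    introgression fields parameterise a simplified three-population
    (African / European / archaic) stand-in model.
    """

    scenario: str = SCENARIO_POSITIVE
    s: float = 0.05
    h: float | None = None
    t_onset: float = 1_000.0
    rescale_Q: float = 1.0
    restart_cap: int = 10_000
    seed: int | None = None
    # adaptive-introgression stand-in model
    pulse_fraction: float = 0.02
    pulse_time: float = 2_000.0
    eur_split_time: float = 2_500.0
    archaic_split_time: float = 16_000.0
    archaic_size: float = 2_500.0

    def __post_init__(self) -> None:
        if self.scenario not in (
            SCENARIO_POSITIVE, SCENARIO_BALANCING, SCENARIO_INTROGRESSION
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.t_onset <= 0:
            raise ValueError("t_onset must be positive")
        if self.rescale_Q < 1:
            raise ValueError("rescale_Q must be >= 1")
        if self.h is None:
            self.h = 2.0 if self.scenario == SCENARIO_BALANCING else 0.5


class SweepConditioningError(RuntimeError):
    """Raised when the restart budget is exhausted before reaching present."""


# ---------------------------------------------------------------------------
# Forward Wright-Fisher trajectory at the selected site
# ---------------------------------------------------------------------------

def wf_trajectory(
    sizes: np.ndarray,
    s: float,
    h: float,
    rng: np.random.Generator,
    initial_freq: float | None = None,
    restart_cap: int = 10_000,
    condition_on_segregation: bool = True,
) -> np.ndarray:
    """Forward WF frequency trajectory of the selected allele.

    ``sizes[t]`` is the diploid population size t generations before present,
    for t = 0..T; the allele is introduced at time T (index T), as one copy
    unless ``initial_freq`` is given.  Returns frequencies indexed the same
    way (entry [T] is the initial frequency, entry [0] the present one).

    On loss the offspring generation is re-drawn (restart from the previous
    generation's checkpointed state); the total number of re-draws across the
    simulation is capped by ``restart_cap``.
    """
    T = len(sizes) - 1
    freqs = np.zeros(T + 1)
    n_chrom = 2 * max(int(round(sizes[T])), 1)
    count = max(int(round((initial_freq if initial_freq is not None else 1.0 / n_chrom) * n_chrom)), 1)
    freqs[T] = count / n_chrom
    restarts = 0
    w_AA, w_Aa, w_aa = 1.0 + s, 1.0 + h * s, 1.0
    for t in range(T, 0, -1):  # forward in time: t gens before present -> t-1
        p = freqs[t]
        q = 1.0 - p
        wbar = p * p * w_AA + 2 * p * q * w_Aa + q * q * w_aa
        p_sel = p * (p * w_AA + q * w_Aa) / wbar
        m = 2 * max(int(round(sizes[t - 1])), 1)
        while True:
            nxt = rng.binomial(m, p_sel)
            if nxt > 0 or not condition_on_segregation:
                break
            restarts += 1
            if restarts > restart_cap:
                raise SweepConditioningError(
                    "sweep unconditionable at these parameters "
                    f"(restart cap {restart_cap} exceeded)"
                )
        freqs[t - 1] = nxt / m
        if nxt == 0:
            freqs[: t - 1] = 0.0
            break
    return freqs


def deterministic_trajectory(p0: float, s: float, h: float, n_gen: int) -> np.ndarray:
    """Deterministic one-locus selection recursion (infinite population).

    Iterates p' = p*(w_AA*p + w_Aa*q)/wbar; with over-dominance (h > 1) the
    recursion converges to the interior equilibrium h/(2h-1).
    """
    w_AA, w_Aa, w_aa = 1.0 + s, 1.0 + h * s, 1.0
    p = p0
    out = np.empty(n_gen + 1)
    out[0] = p
    for i in range(1, n_gen + 1):
        q = 1.0 - p
        wbar = p * p * w_AA + 2 * p * q * w_Aa + q * q * w_aa
        p = p * (p * w_AA + q * w_Aa) / wbar
        out[i] = p
    return out


# ---------------------------------------------------------------------------
# Structured-coalescent backward pass
# ---------------------------------------------------------------------------

def _chunk_trajectory(freqs: np.ndarray, max_chunks: int = 48,
                      dx: float = 0.05) -> list[tuple[int, int, float]]:
    """Split the per-generation trajectory into epochs of slowly varying x.

    Returns (t_lo, t_hi, mean_x) tuples with t in generations before present,
    ordered from present backwards, covering [0, T).
    """
    T = len(freqs) - 1
    min_len = max(1, T // max_chunks)
    chunks = []
    t = 0
    while t < T:
        t_hi = t + 1
        while (
            t_hi < T
            and t_hi - t < 4 * min_len
            and abs(freqs[t_hi] - freqs[t]) < dx
        ):
            t_hi += 1
        t_hi = max(t_hi, min(t + min_len, T))
        chunks.append((t, t_hi, float(freqs[t:t_hi].mean())))
        t = t_hi
    return chunks


def _deme_sizes(x: float, N: float) -> tuple[float, float]:
    return (max(x * N, _MIN_DEME_SIZE), max((1.0 - x) * N, _MIN_DEME_SIZE))


def _sweep_demography(
    params: DemographyParams,
    freqs: np.ndarray,
    cfg: SimConfig,
    q: float,
) -> msprime.Demography:
    """Two-background demography conditioned on the (scaled) trajectory."""
    T = len(freqs) - 1  # scaled generations
    r_rate = cfg.recomb_rate()
    if isinstance(r_rate, msprime.RateMap):
        r_rate = float(r_rate.mean_rate)
    r_eff = r_rate * q * cfg.L * _D_EFF_FRACTION

    dem = msprime.Demography()
    N0 = params.size_at(0) / q
    s_sel, s_neu = _deme_sizes(freqs[0], N0)
    dem.add_population(name="sel", initial_size=s_sel)
    dem.add_population(name="neu", initial_size=s_neu)

    chunks = _chunk_trajectory(freqs)
    for (t_lo, t_hi, xbar) in chunks:
        Nbar = params.size_at(0.5 * (t_lo + t_hi) * q) / q
        ds, dn = _deme_sizes(xbar, Nbar)
        if t_lo > 0:
            dem.add_population_parameters_change(
                time=t_lo, population="sel", initial_size=ds)
            dem.add_population_parameters_change(
                time=t_lo, population="neu", initial_size=dn)
        dem.add_migration_rate_change(
            time=t_lo, source="sel", dest="neu", rate=r_eff * (1.0 - xbar))
        dem.add_migration_rate_change(
            time=t_lo, source="neu", dest="sel", rate=r_eff * xbar)

    # onset of selection: remaining carrier lineages join the main population
    dem.add_migration_rate_change(time=T, rate=0.0)
    dem.add_mass_migration(time=T, source="sel", dest="neu", proportion=1.0)
    # neutral history deeper than the forward phase (recapitation contract)
    t_onset_unscaled = T * q
    if t_onset_unscaled < params.T2:
        dem.add_population_parameters_change(
            time=T, population="neu",
            initial_size=params.size_at(t_onset_unscaled) / q,
            growth_rate=params.g * q)
    else:
        dem.add_population_parameters_change(
            time=T, population="neu",
            initial_size=params.size_at(t_onset_unscaled) / q, growth_rate=0.0)
    if params.T2 / q > T:
        dem.add_population_parameters_change(
            time=params.T2 / q, population="neu",
            initial_size=params.N2 / q, growth_rate=0.0)
    dem.add_population_parameters_change(
        time=max(params.T1 / q, T + 1e-9), population="neu",
        initial_size=params.N1 / q)
    dem.sort_events()
    return dem


def _simulate_conditioned(
    params: DemographyParams,
    sel: SelectionConfig,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> HaplotypeRegion | None:
    """One sweep/balancing region (single attempt; None if window empty)."""
    q = sel.rescale_Q
    T = max(int(round(sel.t_onset / q)), 1)
    sizes = np.array([params.size_at(t * q) / q for t in range(T + 1)])
    freqs = wf_trajectory(
        sizes, sel.s * q, sel.h, rng, restart_cap=sel.restart_cap)
    x0 = freqs[0]
    n_sel = int(rng.binomial(cfg.n, x0))
    dem = _sweep_demography(params, freqs, cfg, q)
    seed1, seed2 = _two_seeds(rng)
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n_sel, population="sel", ploidy=1),
            msprime.SampleSet(cfg.n - n_sel, population="neu", ploidy=1),
        ],
        demography=dem,
        sequence_length=cfg.L,
        recombination_rate=_scaled_recomb_rate(cfg, q),
        random_seed=seed1,
    )
    ts = msprime.sim_mutations(ts, rate=cfg.mu * q, random_seed=seed2)
    marker = np.zeros(cfg.n, dtype=np.int8)
    marker[:n_sel] = 1
    return _ts_to_region(
        ts, cfg, LABEL_SELECTED, sel_coeff=sel.s,
        extra_site=(cfg.L // 2, marker),
        info={"carrier_count": int(n_sel), "present_freq": float(x0)},
    )


def _two_seeds(rng: np.random.Generator) -> tuple[int, int]:
    return (int(rng.integers(1, 2**31 - 1)), int(rng.integers(1, 2**31 - 1)))


def _scaled_recomb_rate(cfg: SimConfig, q: float):
    rate = cfg.recomb_rate()
    if isinstance(rate, msprime.RateMap):
        if q != 1.0:
            rate = msprime.RateMap(position=rate.position, rate=rate.rate * q)
        return rate
    return rate * q


def simulate_sweep_region(
    params: DemographyParams,
    sel: SelectionConfig,
    cfg: SimConfig,
    seed: int | None = None,
    max_retries: int = 10,
) -> HaplotypeRegion:
    """Simulate one hard-sweep region (beneficial mutation at bp L/2)."""
    if sel.scenario != SCENARIO_POSITIVE:
        raise ValueError("scenario must be 'positive'")
    return _retry_region(params, sel, cfg, seed, max_retries,
                         _simulate_conditioned)


def simulate_balancing_region(
    params: DemographyParams,
    sel: SelectionConfig,
    cfg: SimConfig,
    seed: int | None = None,
    max_retries: int = 10,
) -> HaplotypeRegion:
    """Simulate one over-dominant balancing-selection region (h = 2)."""
    if sel.scenario != SCENARIO_BALANCING:
        raise ValueError("scenario must be 'balancing'")
    return _retry_region(params, sel, cfg, seed, max_retries,
                         _simulate_conditioned)


def _retry_region(params, sel, cfg, seed, max_retries, fn) -> HaplotypeRegion:
    rng = np.random.default_rng(seed if seed is not None else sel.seed)
    for _ in range(max_retries):
        region = fn(params, sel, cfg, rng)
        if region is not None:
            return region
    raise RuntimeError("no segregating sites after retry budget")


# ---------------------------------------------------------------------------
# Adaptive introgression (simplified three-population stand-in)
# ---------------------------------------------------------------------------

def _introgression_demography(
    params: DemographyParams,
    sel: SelectionConfig,
    freqs: np.ndarray | None,
    cfg: SimConfig,
    q: float,
) -> msprime.Demography:
    r_rate = cfg.recomb_rate()
    if isinstance(r_rate, msprime.RateMap):
        r_rate = float(r_rate.mean_rate)
    r_eff = r_rate * q * cfg.L * _D_EFF_FRACTION

    dem = msprime.Demography()
    N0 = params.size_at(0) / q
    x0 = freqs[0] if freqs is not None else 0.0
    s_sel, s_neu = _deme_sizes(x0, N0)
    dem.add_population(name="sel", initial_size=s_sel)
    dem.add_population(name="neu", initial_size=s_neu)
    dem.add_population(name="afr", initial_size=params.N1 / q)
    dem.add_population(name="arc", initial_size=sel.archaic_size / q)

    T_pulse = max(int(round(sel.pulse_time / q)), 1)
    if freqs is not None:
        for (t_lo, t_hi, xbar) in _chunk_trajectory(freqs):
            Nbar = params.size_at(0.5 * (t_lo + t_hi) * q) / q
            ds, dn = _deme_sizes(xbar, Nbar)
            if t_lo > 0:
                dem.add_population_parameters_change(
                    time=t_lo, population="sel", initial_size=ds)
                dem.add_population_parameters_change(
                    time=t_lo, population="neu", initial_size=dn)
            dem.add_migration_rate_change(
                time=t_lo, source="sel", dest="neu", rate=r_eff * (1 - xbar))
            dem.add_migration_rate_change(
                time=t_lo, source="neu", dest="sel", rate=r_eff * xbar)
        dem.add_migration_rate_change(time=T_pulse, rate=0.0)
        # at the pulse the carriers' ancestry at the focal site is archaic
        dem.add_mass_migration(
            time=T_pulse, source="sel", dest="arc", proportion=1.0)

    # European branch sizes deeper than the pulse
    tp = T_pulse * q
    if tp < params.T2:
        dem.add_population_parameters_change(
            time=T_pulse, population="neu",
            initial_size=params.size_at(tp) / q, growth_rate=params.g * q)
        dem.add_population_parameters_change(
            time=params.T2 / q, population="neu",
            initial_size=params.N2 / q, growth_rate=0.0)
    else:
        dem.add_population_parameters_change(
            time=T_pulse, population="neu",
            initial_size=params.size_at(tp) / q, growth_rate=0.0)
    dem.add_mass_migration(
        time=sel.eur_split_time / q, source="neu", dest="afr", proportion=1.0)
    dem.add_mass_migration(
        time=sel.archaic_split_time / q, source="arc", dest="afr",
        proportion=1.0)
    dem.sort_events()
    return dem


def simulate_adaptive_introgression(
    params: DemographyParams,
    sel: SelectionConfig,
    cfg: SimConfig,
    seed: int | None = None,
    max_retries: int = 10,
) -> HaplotypeRegion:
    """Simulate one adaptive-introgression region; only the n European
    haplotypes are returned.

    An admixture pulse of fraction ``pulse_fraction`` from the archaic branch
    enters the European branch at ``pulse_time``; the introgressed allele at
    bp L/2 is then positively selected (forward WF trajectory starting at the
    pulse fraction, restart-on-loss).  With pulse fraction 0 the model
    reduces to a neutral two-population history for the sampled branch.
    """
    if sel.scenario != SCENARIO_INTROGRESSION:
        raise ValueError("scenario must be 'adaptive_introgression'")

    def attempt(params, sel, cfg, rng):
        q = sel.rescale_Q
        T = max(int(round(sel.pulse_time / q)), 1)
        if sel.pulse_fraction > 0:
            sizes = np.array(
                [params.size_at(t * q) / q for t in range(T + 1)])
            freqs = wf_trajectory(
                sizes, sel.s * q, sel.h, rng,
                initial_freq=sel.pulse_fraction,
                restart_cap=sel.restart_cap)
        else:
            freqs = None
        x0 = freqs[0] if freqs is not None else 0.0
        n_sel = int(rng.binomial(cfg.n, x0))
        dem = _introgression_demography(params, sel, freqs, cfg, q)
        seed1, seed2 = _two_seeds(rng)
        ts = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(n_sel, population="sel", ploidy=1),
                msprime.SampleSet(cfg.n - n_sel, population="neu", ploidy=1),
            ],
            demography=dem,
            sequence_length=cfg.L,
            recombination_rate=_scaled_recomb_rate(cfg, q),
            random_seed=seed1,
        )
        ts = msprime.sim_mutations(ts, rate=cfg.mu * q, random_seed=seed2)
        marker = np.zeros(cfg.n, dtype=np.int8)
        marker[:n_sel] = 1
        return _ts_to_region(
            ts, cfg, LABEL_SELECTED, sel_coeff=sel.s,
            extra_site=(cfg.L // 2, marker),
            info={"carrier_count": int(n_sel), "present_freq": float(x0)},
        )

    return _retry_region(params, sel, cfg, seed, max_retries, attempt)


def simulate_selected_region(
    params: DemographyParams,
    sel: SelectionConfig,
    cfg: SimConfig,
    seed: int | None = None,
) -> HaplotypeRegion:
    """Dispatch to the scenario-specific simulator."""
    fn = {
        SCENARIO_POSITIVE: simulate_sweep_region,
        SCENARIO_BALANCING: simulate_balancing_region,
        SCENARIO_INTROGRESSION: simulate_adaptive_introgression,
    }[sel.scenario]
    return fn(params, sel, cfg, seed=seed)


# ---------------------------------------------------------------------------
# SLiM tree-sequence interop (optional external forward backend)
# ---------------------------------------------------------------------------

def region_from_trees(
    path: str,
    params: DemographyParams,
    cfg: SimConfig,
    sel_coeff: float,
    seed: int | None = None,
    rescale_Q: float = 1.0,
) -> HaplotypeRegion:
    """Encode a forward-simulated .trees file (e.g. from SLiM).

    The tree sequence is recapitated under the neutral demography, simplified
    to n sampled haplotypes, and neutral mutations are overlaid at rate mu --
    the same contract as the native forward path.
    """
    import tskit

    rng = np.random.default_rng(seed)
    ts = tskit.load(path)
    q = rescale_Q
    if max(t.num_roots for t in ts.trees()) > 1:
        dem = _demog.build_demography(params, rescale_Q=q, name="pop")
        # map the forward simulation's population 0 onto the model population
        ts = msprime.sim_ancestry(
            initial_state=ts, demography=dem,
            recombination_rate=_scaled_recomb_rate(cfg, q),
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
    samples = np.asarray(ts.samples())
    if len(samples) > cfg.n:
        keep = rng.choice(samples, size=cfg.n, replace=False)
        ts = ts.simplify(samples=np.sort(keep))
    ts = msprime.sim_mutations(
        ts, rate=cfg.mu * q, random_seed=int(rng.integers(1, 2**31 - 1)),
        keep=True)
    region = _ts_to_region(ts, cfg, LABEL_SELECTED, sel_coeff=sel_coeff)
    if region is None:
        raise RuntimeError("no segregating sites in tree sequence")
    return region


# ---------------------------------------------------------------------------
# Fine-tuning dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FineTuneDataset:
    """Labeled neutral (0) vs selected (1) regions with an 80/20 split."""

    regions: list[HaplotypeRegion]
    labels: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    scenario: str
    counts: dict

    def __post_init__(self) -> None:
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (neutral) or 1 (selected)")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def subset_tensors(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from .regions import stack_tensors

        return (stack_tensors([self.regions[i] for i in idx]),
                self.labels[idx].astype(np.float64))


def build_finetune_dataset(
    params: DemographyParams,
    cfg: SimConfig,
    scenario: str = SCENARIO_POSITIVE,
    counts: dict | None = None,
    seed: int | None = None,
    rescale_Q: float = 1.0,
    val_fraction: float = VALIDATION_FRACTION,
    **sel_kwargs,
) -> FineTuneDataset:
    """Simulate and label a fine-tuning dataset with a seeded 80/20 split.

    ``counts`` defaults to 3,000 neutral regions plus 600 per selection
    coefficient in {0.01, 0.025, 0.05, 0.1}; pass e.g.
    ``{"neutral": 300, "selected": {0.05: 120, 0.1: 120}}`` to override.
    """
    if counts is None:
        counts = {
            "neutral": DATASET_N_NEUTRAL,
            "selected": {s: DATASET_N_PER_COEFF for s in DATASET_SEL_COEFFS},
        }
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(
        counts["neutral"] + sum(counts["selected"].values()) + 1,
        dtype=np.uint32))
    regions: list[HaplotypeRegion] = []
    labels: list[int] = []
    for i in range(counts["neutral"]):
        sd = int(next(seeds)) % (2**31 - 1)
        try:
            regions.append(_demog.simulate_neutral_region(
                params, cfg, seed=sd, rescale_Q=rescale_Q))
        except Exception:
            logger.error("neutral simulation failed at seed %d", sd)
            raise
        labels.append(0)
    for s_val, n_req in counts["selected"].items():
        sel = SelectionConfig(scenario=scenario, s=float(s_val),
                              rescale_Q=rescale_Q, **sel_kwargs)
        for i in range(n_req):
            sd = int(next(seeds)) % (2**31 - 1)
            try:
                regions.append(
                    simulate_selected_region(params, sel, cfg, seed=sd))
            except Exception:
                logger.error("%s simulation (s=%g) failed at seed %d",
                             scenario, s_val, sd)
                raise
            labels.append(1)
    labels_arr = np.asarray(labels, dtype=np.int8)
    rng = np.random.default_rng(int(next(seeds)))
    perm = rng.permutation(len(regions))
    n_val = int(round(val_fraction * len(regions)))
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    per_class = {
        "neutral": counts["neutral"],
        "selected_total": int(labels_arr.sum()),
        "selected": dict(counts["selected"]),
        "validation": n_val,
    }
    return FineTuneDataset(
        regions=regions, labels=labels_arr, train_idx=train_idx,
        val_idx=val_idx, scenario=scenario, counts=per_class,
    )
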
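"""Neutral 50 kb regions under a five-parameter exponential-growth demography.

The single-population model has ancestral size N1 until a bottleneck at T1
generations before present, bottleneck size N2 until T2, then exponential
growth at per-generation rate g from N2 forward in time over the last T2
generations (present-day size N2*exp(g*T2)).

This module also provides the simulated-annealing proposal kernel used by the
adversarial trainer: one parameter at a time is perturbed by a symmetric
Gaussian whose width is proportional to temperature times the parameter range.
"""

from __future__ import annotations

import dataclasses
import math

import msprime
import numpy as np

from .regions import LABEL_NEUTRAL, HaplotypeRegion, region_from_01

DEFAULT_MU = 1.25e-8
DEFAULT_RECOMB = 1.25e-8
DEFAULT_L = 50_000
DEFAULT_S = 36

#: growth-rate cap applied in all simulations (uncapped growth makes forward
#: selection simulations under the fitted model intractably large)
G_CAP = 0.01


@dataclasses.dataclass
class DemographyParams:
    """Exponential-growth model parameters (sizes in diploids, times in
    generations before present)."""

    N1: float
    N2: float
    g: float
    T1: float
    T2: float
    g_cap: float = G_CAP
    T2_cap: float | None = None

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("population sizes must be positive")
        if not (self.T1 > self.T2 > 0):
            raise ValueError("require T1 > T2 > 0")
        if not (0 <= self.g <= self.g_cap):
            raise ValueError(f"growth rate must lie in [0, {self.g_cap}]")
        if self.T2_cap is not None and self.T2 > self.T2_cap:
            raise ValueError("T2 exceeds its configured cap")

    def size_at(self, t: float) -> float:
        """Diploid population size t generations before present."""
        if t >= self.T1:
            return self.N1
        if t >= self.T2:
            return self.N2
        return self.N2 * math.exp(self.g * (self.T2 - t))


#: point estimates fitted for three human populations (sizes in diploids,
#: times in generations); used as defaults for simulation studies.
FITTED_PARAMS = {
    "CEU": DemographyParams(N1=22_552, N2=3_313, g=0.00535, T1=3_589, T2=1_050),
    "CHB": DemographyParams(N1=24_609, N2=3_481, g=0.00404, T1=4_417, T2=1_024),
    "YRI": DemographyParams(N1=23_231, N2=29_962, g=0.00531, T1=4_870, T2=581,
                            T2_cap=750),
}


@dataclasses.dataclass
class ParamRanges:
    """Per-parameter (low, high) bounds for initialization and SA proposals.

    ``present_cap`` bounds the implied present-day size N2*exp(g*T2): points
    beyond it are numerically hostile (coalescent simulation cost grows with
    N*r*L) and far outside the plausible human parameter space.
    """

    N1: tuple[float, float] = (1_000, 60_000)
    N2: tuple[float, float] = (500, 60_000)
    g: tuple[float, float] = (0.0, G_CAP)
    T1: tuple[float, float] = (1_000, 8_000)
    T2: tuple[float, float] = (100, 2_000)
    present_cap: float = 2e6

    def __post_init__(self) -> None:
        for name in ("N1", "N2", "g", "T1", "T2"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")

    def _enforce_present_cap(self, vals: dict) -> dict:
        growth_total = vals["g"] * vals["T2"]
        limit = math.log(self.present_cap / vals["N2"])
        if growth_total > limit:
            vals["g"] = max(limit, 0.0) / vals["T2"]
        return vals

    def clip(self, params: DemographyParams) -> DemographyParams:
        vals = {}
        for name in ("N1", "N2", "g", "T1", "T2"):
            lo, hi = getattr(self, name)
            vals[name] = float(np.clip(getattr(params, name), lo, hi))
        vals["g"] = min(vals["g"], params.g_cap)
        if params.T2_cap is not None:
            vals["T2"] = min(vals["T2"], params.T2_cap)
        if vals["T2"] >= vals["T1"]:  # keep epoch ordering after clipping
            vals["T2"] = vals["T1"] * 0.5
        vals = self._enforce_present_cap(vals)
        return DemographyParams(
            g_cap=params.g_cap, T2_cap=params.T2_cap, **vals
        )

    def sample(self, rng: np.random.Generator) -> DemographyParams:
        draw = {
            name: rng.uniform(*getattr(self, name))
            for name in ("N1", "N2", "g", "T1", "T2")
        }
        if draw["T2"] >= draw["T1"]:
            draw["T2"] = draw["T1"] * 0.5
        draw = self._enforce_present_cap(draw)
        return DemographyParams(**draw)


@dataclasses.dataclass
class SimConfig:
    """Shared simulation settings for one study."""

    n: int
    mu: float = DEFAULT_MU
    L: int = DEFAULT_L
    S: int = DEFAULT_S
    recomb: float | str = DEFAULT_RECOMB  # constant rate, or HapMap map path
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0 or self.L <= 0 or self.S <= 0:
            raise ValueError("n, L, S must all be positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")

    def recomb_rate(self):
        if isinstance(self.recomb, str):
            return msprime.RateMap.read_hapmap(self.recomb)
        return self.recomb


def build_demography(
    params: DemographyParams, rescale_Q: float = 1.0, name: str = "pop"
) -> msprime.Demography:
    """Build the single-population msprime demography, optionally rescaled.

    With rescaling factor Q, sizes are divided by Q, times divided by Q and
    the growth rate multiplied by Q, leaving N*g and the epoch structure of
    the coalescent invariant.
    """
    q = float(rescale_Q)
    dem = msprime.Demography()
    present = params.N2 * math.exp(params.g * params.T2)
    dem.add_population(name=name, initial_size=present / q,
                       growth_rate=params.g * q)
    dem.add_population_parameters_change(
        time=params.T2 / q, population=name,
        initial_size=params.N2 / q, growth_rate=0.0)
    dem.add_population_parameters_change(
        time=params.T1 / q, population=name, initial_size=params.N1 / q)
    return dem


def _ts_to_region(ts, cfg: SimConfig, label: str, sel_coeff: float = 0.0,
                  extra_site: tuple[int, np.ndarray] | None = None,
                  info: dict | None = None) -> HaplotypeRegion | None:
    """Extract biallelic segregating sites from a tree sequence and encode.

    ``extra_site`` optionally injects one (position, 0/1 column) variant —
    used for the selected/marker allele in non-neutral simulations.
    """
    cols: list[np.ndarray] = []
    poss: list[int] = []
    n = ts.num_samples
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        g = var.genotypes
        ones = int(g.sum())
        if ones == 0 or ones == n:
            continue
        pos = int(var.site.position)
        if poss and pos <= poss[-1]:
            continue  # collapse same-bp sites; keep the first
        cols.append(g.astype(np.int8))
        poss.append(pos)
    if extra_site is not None:
        pos, col = extra_site
        ones = int(col.sum())
        if 0 < ones < n and pos not in poss:
            idx = int(np.searchsorted(poss, pos))
            poss.insert(idx, pos)
            cols.insert(idx, col.astype(np.int8))
    if not cols:
        return None
    h = np.stack(cols, axis=1)
    return region_from_01(
        h, np.asarray(poss), chrom="sim", start=0, end=cfg.L,
        label=label, sel_coeff=sel_coeff, S=cfg.S, info=info,
    )


def simulate_neutral_ts(
    params: DemographyParams,
    cfg: SimConfig,
    seed: int | None = None,
    rescale_Q: float = 1.0,
):
    """Simulate one neutral tree sequence over the full L bp region."""
    q = float(rescale_Q)
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1
              for s in ss.spawn(2))
    # haploid sample sets under the diploid model: n sampled haplotypes,
    # coalescent time scale 2N
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(cfg.n, population="pop", ploidy=1)],
        demography=build_demography(params, rescale_Q=q),
        sequence_length=cfg.L, recombination_rate=_scaled_recomb(cfg, q),
        random_seed=s1,
    )
    return msprime.sim_mutations(ts, rate=cfg.mu * q, random_seed=s2)


def simulate_neutral_region(
    params: DemographyParams,
    cfg: SimConfig,
    seed: int | None = None,
    rescale_Q: float = 1.0,
    max_retries: int = 10,
) -> HaplotypeRegion:
    """Simulate one neutral region and encode its middle S SNPs.

    Regions with zero segregating sites are retried with fresh seeds up to
    ``max_retries`` times before raising.
    """
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    for child in ss.spawn(max_retries):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        ts = simulate_neutral_ts(params, cfg, seed=sub, rescale_Q=rescale_Q)
        region = _ts_to_region(ts, cfg, LABEL_NEUTRAL)
        if region is not None:
            return region
    raise RuntimeError("no segregating sites after retry budget")


def _scaled_recomb(cfg: SimConfig, q: float):
    rate = cfg.recomb_rate()
    if isinstance(rate, msprime.RateMap):
        if q != 1.0:
            rate = msprime.RateMap(position=rate.position, rate=rate.rate * q)
        return rate
    return rate * q


_PARAM_NAMES = ("N1", "N2", "g", "T1", "T2")


def propose_params(
    current: DemographyParams,
    ranges: ParamRanges,
    temperature: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    free_params: tuple[str, ...] = _PARAM_NAMES,
    width_frac: float = 0.1,
) -> DemographyParams:
    """Perturb one randomly chosen parameter with a symmetric Gaussian kernel.

    The kernel standard deviation is ``temperature * width_frac * (high-low)``
    for the chosen parameter; the result is clipped to the ranges and to the
    growth/T2 caps.  Temperature 0 returns ``current`` unchanged.
    """
    if not 0 <= temperature <= 1:
        raise ValueError("temperature must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if temperature == 0 or not free_params:
        return current
    name = free_params[rng.integers(len(free_params))]
    lo, hi = getattr(ranges, name)
    vals = {p: getattr(current, p) for p in _PARAM_NAMES}
    vals[name] = vals[name] + rng.normal(0.0, temperature * width_frac * (hi - lo))
    vals[name] = float(np.clip(vals[name], lo, hi))
    # rebuild through clip() so epoch ordering and caps are enforced
    try:
        cand = DemographyParams(g_cap=current.g_cap, T2_cap=current.T2_cap, **vals)
    except ValueError:
        cand = ranges.clip(
            DemographyParams(
                N1=max(vals["N1"], 1.0), N2=max(vals["N2"], 1.0),
                g=min(max(vals["g"], 0.0), current.g_cap),
                T1=max(vals["T1"], 2.0),
                T2=min(max(vals["T2"], 1.0), max(vals["T1"], 2.0) * 0.5),
                g_cap=current.g_cap, T2_cap=current.T2_cap,
            )
        )
    return ranges.clip(cand)
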
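"""Shared fixtures: small demographies, simulated region sets, and a
once-per-session adversarially trained discriminator.

Everything is generated programmatically with fixed seeds; simulation sizes
are kept small so the whole suite runs on one CPU.
"""

import numpy as np
import pytest

import discscan as ds
from discscan import demography as dg
from discscan import network as nw
from discscan import selection as sl
from discscan import training as tr
from discscan.regions import stack_tensors


@pytest.fixture(scope="session")
def ceu_params():
    return dg.FITTED_PARAMS["CEU"]


@pytest.fixture(scope="session")
def const_params():
    """Constant-size model (no bottleneck, no growth) for closed-form checks."""
    return dg.DemographyParams(N1=10_000, N2=10_000, g=0.0, T1=2_000, T2=1_000)


@pytest.fixture(scope="session")
def small_cfg():
    return dg.SimConfig(n=32)


@pytest.fixture(scope="session")
def neutral_regions(ceu_params, small_cfg):
    """120 neutral CEU regions at n=32 used across tests."""
    return [
        dg.simulate_neutral_region(ceu_params, small_cfg, seed=10_000 + i)
        for i in range(120)
    ]


@pytest.fixture(scope="session")
def sweep_regions(ceu_params, small_cfg):
    """60 strong-sweep regions (s=0.1) at n=32."""
    sel = sl.SelectionConfig(scenario="positive", s=0.1)
    return [
        sl.simulate_sweep_region(ceu_params, sel, small_cfg, seed=20_000 + i)
        for i in range(60)
    ]


@pytest.fixture(scope="session")
def tiny_dataset(ceu_params, small_cfg):
    """Small labeled fine-tuning dataset (neutral vs sweeps) at n=32."""
    counts = {"neutral": 150, "selected": {0.05: 40, 0.1: 40}}
    return sl.build_finetune_dataset(
        ceu_params, small_cfg, counts=counts, seed=33)


@pytest.fixture(scope="session")
def gan_state(neutral_regions, small_cfg):
    """A small adversarially trained (non-degenerate) discriminator.

    Trained once per session: the 120 neutral fixture regions act as the
    "real" data and the generator searches a narrow box around the fitted
    parameters.
    """
    ranges = dg.ParamRanges(
        N1=(15_000, 30_000), N2=(1_500, 8_000), g=(0.0, 0.01),
        T1=(2_500, 4_500), T2=(600, 1_500))
    sa = tr.SAConfig(iterations=10, batch_size=20, disc_updates_per_iter=3,
                     seed=5)
    state, params, trace = tr.train_gan(
        neutral_regions, ranges, small_cfg, sa,
        initial_params=dg.FITTED_PARAMS["CEU"], free_params=("N1", "N2"))
    return state


@pytest.fixture(scope="session")
def zero_state():
    state = nw.build_discriminator(nw.DiscriminatorSpec(), seed=0)
    for key in state.weights:
        state.weights[key][:] = 0.0
    return state


@pytest.fixture(scope="session")
def random_batch():
    """A (8, 16, 36, 2) batch of valid-looking coded tensors."""
    rng = np.random.default_rng(99)
    x = rng.choice([-1.0, 1.0], size=(8, 16, 36, 2)).astype(np.float32)
    x[..., 1] = np.abs(x[..., 1]) * 0.005
    x[..., 1] = x[:, :1, :, 1]  # distance channel identical down the rows
    return x


def pi_allpairs(region):
    """Independent pi oracle: mean pairwise Hamming distance over all pairs."""
    g = region.genotypes[:, : region.n_snps]
    n = g.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((g[i] != g[j]).sum())
            pairs += 1
    return total / pairs
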
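"""Forward selection simulator: conditioning, diversity reduction,
balancing equilibrium, introgression, dataset assembly."""

import numpy as np
import pytest

import msprime

from discscan import demography as dg
from discscan import selection as sl
from discscan.regions import LABEL_SELECTED


def window_pi(region):
    g = region.genotypes[:, : region.n_snps]
    n = g.shape[0]
    p = (g == 1).sum(axis=0) / n
    return float((2 * p * (1 - p) * n / (n - 1)).sum())


class TestTrajectory:
    def test_conditioned_on_non_loss(self):
        """The selected allele is never lost between introduction and present."""
        rng = np.random.default_rng(0)
        sizes = np.full(301, 500.0)
        for _ in range(200):
            f = sl.wf_trajectory(sizes, 0.02, 0.5, rng)
            assert np.all(f > 0)

    def test_restart_cap_raises(self):
        rng = np.random.default_rng(1)
        sizes = np.full(501, 3.0)
        with pytest.raises(sl.SweepConditioningError, match="unconditionable"):
            for _ in range(200):  # a loss occurs almost immediately at N=3
                sl.wf_trajectory(sizes, 0.0, 0.5, rng, restart_cap=0)

    def test_deterministic_recursion_equilibrium(self):
        """Over-dominance h=2 converges to h/(2h-1) = 2/3."""
        traj = sl.deterministic_trajectory(0.1, 0.05, 2.0, 3_000)
        assert traj[-1] == pytest.approx(2 / 3, abs=1e-6)

    def test_balancing_stochastic_equilibrium(self):
        """Mean final frequency at large N, s=0.05, h=2 is near 2/3."""
        rng = np.random.default_rng(2)
        sizes = np.full(2_001, 10_000.0)
        finals = [sl.wf_trajectory(sizes, 0.05, 2.0, rng)[0]
                  for _ in range(100)]
        assert abs(np.mean(finals) - 2 / 3) < 0.1


class TestSweep:
    def test_label_and_coefficient(self, sweep_regions):
        for r in sweep_regions[:10]:
            assert r.label == LABEL_SELECTED
            assert r.sel_coeff == 0.1

    def test_neutral_equivalence_at_s_zero(self, ceu_params, small_cfg,
                                           neutral_regions):
        """s=0 sweeps are statistically indistinguishable from neutral."""
        sel = sl.SelectionConfig(scenario="positive", s=0.0)
        sw0 = [sl.simulate_sweep_region(ceu_params, sel, small_cfg,
                                        seed=40_000 + i) for i in range(80)]
        a = np.array([window_pi(r) for r in neutral_regions[:80]])
        b = np.array([window_pi(r) for r in sw0])
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_strong_sweep_reduces_diversity(self, neutral_regions,
                                            sweep_regions):
        a = np.mean([window_pi(r) for r in neutral_regions[:60]])
        b = np.mean([window_pi(r) for r in sweep_regions])
        assert b < a

    def test_dataset_coefficients_are_canonical(self):
        assert sl.DATASET_SEL_COEFFS == (0.01, 0.025, 0.05, 0.1)

    def test_scenario_mismatch_rejected(self, ceu_params, small_cfg):
        sel = sl.SelectionConfig(scenario="balancing", s=0.05)
        with pytest.raises(ValueError):
            sl.simulate_sweep_region(ceu_params, sel, small_cfg, seed=1)

    def test_hybrid_matches_exact_sweep_model(self):
        """Dual route: window diversity of the trajectory-conditioned
        structured coalescent agrees with msprime's exact genic sweep model
        when both complete a sweep at present (constant N)."""
        N, L, rate, n = 10_000, 50_000, 1.25e-8, 48
        cfg = dg.SimConfig(n=n)

        def oracle(seed):
            sweep = msprime.SweepGenicSelection(
                position=L / 2, start_frequency=1 / (2 * N),
                end_frequency=1 - 1 / (2 * N), s=0.05, dt=1e-6)
            ts = msprime.sim_ancestry(
                samples=[msprime.SampleSet(n, ploidy=1)], population_size=N,
                sequence_length=L, recombination_rate=rate,
                model=[sweep, msprime.StandardCoalescent()], random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=rate, random_seed=seed + 77)
            return dg._ts_to_region(ts, cfg, LABEL_SELECTED)

        params = dg.DemographyParams(N1=N, N2=N, g=0, T1=50_000, T2=25_000)

        def hybrid(seed):
            rng = np.random.default_rng(seed)
            while True:
                f = sl.wf_trajectory(np.full(8_001, float(N)), 0.05, 0.5, rng)
                fixed = np.flatnonzero(f >= 1.0)
                if fixed.size:
                    traj = f[fixed.max():]
                    break
            dem = sl._sweep_demography(params, traj, cfg, 1.0)
            ts = msprime.sim_ancestry(
                samples=[msprime.SampleSet(n, population="sel", ploidy=1),
                         msprime.SampleSet(0, population="neu", ploidy=1)],
                demography=dem, sequence_length=L, recombination_rate=rate,
                random_seed=int(rng.integers(1, 2**31 - 1)))
            ts = msprime.sim_mutations(
                ts, rate=rate, random_seed=int(rng.integers(1, 2**31 - 1)))
            return dg._ts_to_region(ts, cfg, LABEL_SELECTED)

        a = np.array([window_pi(oracle(i + 1)) for i in range(100)])
        b = np.array([window_pi(hybrid(50_000 + i)) for i in range(100)])
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) < 4 * se

    def test_rescaling_consistency(self, ceu_params):
        """Mean window diversity agrees between Q=1 and Q=5 sweeps."""
        cfg = dg.SimConfig(n=24)
        out = {}
        for q in (1.0, 5.0):
            sel = sl.SelectionConfig(scenario="positive", s=0.05, rescale_Q=q)
            out[q] = np.array([
                window_pi(sl.simulate_sweep_region(
                    ceu_params, sel, cfg, seed=60_000 + i))
                for i in range(60)
            ])
        se = np.sqrt(out[1.0].var() / 60 + out[5.0].var() / 60)
        assert abs(out[1.0].mean() - out[5.0].mean()) < 4 * se


class TestBalancing:
    def test_h_defaults_to_two(self):
        sel = sl.SelectionConfig(scenario="balancing", s=0.05)
        assert sel.h == 2.0

    def test_region_simulates(self, ceu_params, small_cfg):
        sel = sl.SelectionConfig(scenario="balancing", s=0.05)
        r = sl.simulate_balancing_region(ceu_params, sel, small_cfg, seed=5)
        assert r.tensor().values.shape == (32, 36, 2)
        assert r.label == LABEL_SELECTED


class TestIntrogression:
    def test_zero_pulse_reduces_to_neutral_two_pop(self, ceu_params,
                                                   small_cfg):
        sel = sl.SelectionConfig(scenario="adaptive_introgression", s=0.1,
                                 pulse_fraction=0.0)
        r = sl.simulate_adaptive_introgression(ceu_params, sel, small_cfg,
                                               seed=6)
        assert r.info["carrier_count"] == 0  # no archaic-derived variant

    def test_marker_frequency_increases_with_s(self, ceu_params, small_cfg):
        freqs = {}
        for s_val in (0.0, 0.1):
            sel = sl.SelectionConfig(scenario="adaptive_introgression",
                                     s=s_val)
            freqs[s_val] = np.mean([
                sl.simulate_adaptive_introgression(
                    ceu_params, sel, small_cfg, seed=70_000 + i
                ).info["present_freq"]
                for i in range(60)
            ])
        assert freqs[0.1] > freqs[0.0]

    def test_only_focal_population_returned(self, ceu_params, small_cfg):
        sel = sl.SelectionConfig(scenario="adaptive_introgression", s=0.05)
        r = sl.simulate_adaptive_introgression(ceu_params, sel, small_cfg,
                                               seed=8)
        assert r.tensor().values.shape == (small_cfg.n, 36, 2)


class TestFineTuneDataset:
    def test_tiny_dataset_counts_and_split(self, tiny_dataset):
        ds = tiny_dataset
        assert ds.n_regions == 230
        assert int(ds.labels.sum()) == 80
        assert len(ds.val_idx) == round(0.2 * 230)
        assert set(np.concatenate([ds.train_idx, ds.val_idx])) == set(
            range(230))
        sel_regions = [ds.regions[i] for i in np.flatnonzero(ds.labels == 1)]
        assert {r.sel_coeff for r in sel_regions} == {0.05, 0.1}

    def test_split_determinism(self, ceu_params):
        cfg = dg.SimConfig(n=12)
        counts = {"neutral": 12, "selected": {0.1: 6}}
        a = sl.build_finetune_dataset(ceu_params, cfg, counts=counts, seed=9)
        b = sl.build_finetune_dataset(ceu_params, cfg, counts=counts, seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.val_idx, b.val_idx)
        for ra, rb in zip(a.regions, b.regions):
            assert np.array_equal(ra.genotypes, rb.genotypes)

    def test_labels_binary(self, tiny_dataset):
        assert set(np.unique(tiny_dataset.labels)) <= {0, 1}
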
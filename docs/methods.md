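# Methods

This note documents the models, numerical choices and open design decisions
behind `discscan`, and what the test suite does and does not establish.

## Window encoding

A window is the middle S = 36 biallelic segregating SNPs of a region (real
windows: consecutive disjoint blocks of 36 SNPs passing a ≥ 50% accessibility
filter; simulated windows: the middle 36 SNPs of a 50 kb region, with the
offset floored when the remainder is odd). The minor allele is coded +1 and
the major allele −1; at an exact 50/50 tie the ALT (or derived) allele is
coded +1, keeping the encoding deterministic. Windows with fewer than 36
SNPs are right-padded with zero columns in both channels. The second channel
holds the left-adjacent inter-SNP gap (entry 0 is 0; entries 1..35 hold
gaps), rescaled by a fixed 50,000 bp span and clipped to [0, 1]. A fixed
denominator — rather than per-window normalization — keeps SNP density
comparable between real windows (variable bp span) and simulated ones, which
is the channel's purpose. Coordinates are 0-based half-open internally; VCF
positions are converted on ingest. Unphased or missing genotypes are
rejected, not imputed; non-biallelic records are dropped.

## Neutral demographic model

A single population of diploid size N1 until a bottleneck at T1 generations
before present, size N2 until T2, then exponential growth at rate g per
generation, giving present size N2·e^(g·T2). Simulations use msprime with
mutation rate μ = 1.25×10⁻⁸ /bp/generation, region length L = 50 kb and, in
synthetic/test mode, a constant recombination rate 1.25×10⁻⁸ (a HapMap-format
map is used when a map file is supplied; constant-rate defaults keep the test
path download-free). Fitted parameter points for CEU, CHB and YRI are
shipped as defaults for simulation studies. The growth-rate cap 0.01 (and
the YRI cap T2 ≤ 750) are enforced as parameter invariants. The parameter
search space additionally caps the implied present size N2·e^(g·T2) at 2×10⁶
diploids: beyond that the parameter point is both biologically implausible
and numerically hostile (coalescent cost grows with N·r·L).

Population-size rescaling by a factor Q ≥ 1 replaces N → N/Q, t → t/Q,
g → g·Q, μ → μ·Q, r → r·Q and s → s·Q, leaving θ = 4Nμ, ρ and the scaled
drift process invariant. Sweep simulations are fast enough here that the
default is Q = 1 (no rescaling, no distortion of s).

## Selection simulations

Each non-neutral region couples two stages.

**Forward stage.** The frequency of the selected allele at the focal site
(centre of the region, bp L/2) follows a diploid Wright–Fisher simulation:
with frequency p and genotype fitnesses (1, 1+hs, 1+s), the next generation's
allele count is binomial with 2N(t+1) trials and post-selection probability
p(w_AA·p + w_Aa·q)/w̄. The mutation enters as a single copy t_onset = 1,000
generations before present (positive and balancing selection) or at the
admixture-pulse frequency (introgression). If the allele is lost in any
generation, the state is restored to the previous generation and that
generation is re-drawn with fresh randomness; a global cap (default 10,000
re-draws) turns pathological parameter regimes into an explicit
"unconditionable" error rather than a livelock. Dominance is h = 0.5 (genic)
for sweeps and h = 2.0 (heterozygote advantage) for balancing selection; the
over-dominant recursion has interior equilibrium h/(2h−1) = 2/3, which the
stochastic trajectories approach and the tests verify against the
deterministic recursion. No conditioning is applied beyond non-loss; alleles
fixed by the present simply do not segregate in the sample.

**Backward stage.** Conditional on the trajectory x(t), sampled haplotypes
follow a structured coalescent with two backgrounds: carriers (size N(t)x(t))
and non-carriers (size N(t)(1−x(t))). A lineage changes background by
recombination between the focal site and the selected site; this is
approximated with a single effective rate r·d_eff·(frequency of the other
background) per generation, with d_eff = L/4, the mean distance of a
uniformly placed site from the centre. The trajectory is discretized into
epochs of slowly varying x (≤ ~48 chunks). At the onset of selection any
remaining carrier lineages merge into the main population, whose deeper
history is the neutral demography — the recapitation contract — and neutral
mutations are overlaid at rate μ afterwards. The selected (or introgressed
marker) allele is added as a derived variant at L/2 when it segregates in
the sample. The d_eff = L/4 approximation was validated against msprime's
exact genic-sweep structured coalescent at matched conditions (constant
N = 10⁴, s = 0.05, sweep completing at present): window diversity agrees
within sampling error, and the agreement degrades if d_eff is made smaller.
A full haplotype-resolved forward simulation is configuration-reachable only
through the external `.trees` reader (below); under the fitted growth models
the present-day population is ~10⁶ diploids, far beyond what a native
per-haplotype simulation could cover at realistic s without extreme
rescaling.

**Adaptive introgression** uses a deliberately simplified three-population
stand-in: an African branch (constant N1), a European branch following the
fitted demography, an archaic branch (size 2,500) splitting 16,000
generations ago, and a single-generation pulse (default fraction 0.02) into
the European branch 2,000 generations ago, after which the introgressed
allele is positively selected. Only the European haplotypes are returned.
Split times and the pulse fraction are configuration, not fitted values.

**External forward backend.** A `.trees` tree-sequence file produced by a
forward simulator (e.g. SLiM) can be recapitated under the neutral
demography, simplified to n haplotypes, overlaid with neutral mutations and
encoded through the same path.

## Discriminator and training

The exchangeable CNN is implemented directly on NumPy (convolutions as
per-tap GEMMs on strided views; hand-written backpropagation; Adam with step
10⁻³, β₁ = 0.9, β₂ = 0.999). Exchangeability holds exactly: convolutions and
pooling act along the SNP axis only and the haplotype axis is reduced by a
sum. For inference the haplotype rows are first sorted into a canonical
order so that floating-point summation order — and therefore the output —
is bit-identical under any row permutation. Weights are Glorot-uniform
initialized from a seed; training runs in float32. Dropout (rate 0.5 after
each dense layer) is active during training and disabled for prediction and
hidden-unit extraction (taken post-ReLU at the second 128-unit layer).
Unpadded convolutions are forced by the parameter count: the SNP axis
evolves 36 → 32 → 16 → 12 → 6, giving 384 features and 76,577 parameters in
total.

Adversarial training alternates simulated-annealing proposals for the
demographic parameters (one parameter at a time, Gaussian kernel with
standard deviation temperature × 0.1 × range, clipped to bounds and caps)
with discriminator gradient steps on fresh real (label 1) vs simulated
(label 0) batches. The generator objective is the mean discriminator
probability on regions simulated at the candidate point — directly "how
realistic does the discriminator find this parameter point" — and invalid
points (no segregating sites after 10 retries) score 0. Cooling is linear to
zero; the final 10% of the schedule is run greedily (improvements only),
because with proposal width proportional to temperature the Metropolis ratio
exp(Δ/T) does not itself vanish as T → 0. Desk-scale defaults (300
iterations × 5 updates × batch 50) are far below a full study, which is
reachable by configuration only. Discriminators that output a near-constant
value (spread < 10⁻⁴ over ≥ 50 diverse probe regions) are flagged as
degenerate and excluded; fine-tuning refuses them outright, since continued
training cannot rescue a network that ignores its input.

Fine-tuning uses the fixed schedule of 2,000 mini-batches of size 50 drawn
from the 80% train split (the fixed batch schedule, not an epoch count, is
the normative quantity), binary cross-entropy with 0 = neutral / 1 =
selected, validation metrics recorded every 100 batches, early stopping off.

## Scan, candidates and validation

The ensemble prediction for a window is the arithmetic mean over all
retained discriminators. Smoothing is a centered five-window mean, truncated
at chromosome edges and never crossing chromosome boundaries. Candidate
regions are maximal runs of consecutive windows whose smoothed probability
exceeds the threshold (default 0.75 — an illustrative operating point;
outputs are not calibrated probabilities). The permutation test re-places
each truth interval uniformly at random in the scanned coordinate space
(chromosomes weighted by available span; placements independent, overlaps
allowed; interval lengths preserved) and compares the observed mean smoothed
probability inside truth regions with the permuted null; windows count as
"inside" with ≥ 1 bp of overlap, and averaging is per window, not per base
pair. The difference-of-means test is Welch's unequal-variance t-test.

## Interpretability

The 61-statistic vector per region: folded-SFS entries for minor-allele
counts 1–9 (raw counts per window, non-segregating sites excluded); the 35
rescaled inter-SNP distances (exactly the network's distance channel); 15 LD
statistics; pairwise heterozygosity π = Σ 2p̂(1−p̂)·n/(n−1) (the unbiased
per-site estimator summed over the window); and the number of unique
haplotype rows. The 15 LD statistics are defined here as mean r² over SNP
pairs binned by index separation (bin edges chosen once per S to equalize
pair counts); this is a documented stand-in for "fifteen LD statistics",
whose exact upstream definition is not restated anywhere accessible to this
package. Pearson correlations are computed between the 61 statistics and
the 128 last-hidden-layer activations plus the final probability;
zero-variance columns (dead ReLU units) yield a flagged 0 rather than NaN.
Columns are ordered for display by average-linkage agglomerative clustering
on Euclidean distances between correlation profiles.

## Problem sizes used by the shipped experiments

The acceptance experiment (random initialization + standard fine-tuning
schedule, AUC on held-out simulated regions) uses 100 haplotypes per region
and 1,500 neutral + 300 regions per selection coefficient — half the
standard region counts and about half the haplotypes of a full human-panel
study — so it completes on a single CPU in minutes. At this scale the
pooled AUC sits near the full-scale value, with the weakest class
(s = 0.01) at chance, as expected for weak selection over 1,000 generations.
The toy-genome workflow uses 120 windows of 32 haplotypes with ~5% planted
sweeps at s ∈ {0.05, 0.1}, one small adversarial run, a 250-batch
fine-tune, and a 100-permutation test.

## What the synthetic data do not capture

The generators emulate clean, phased, fully ascertained haplotype data under
a single-population (or stylized three-population) history with constant
mutation rate and (by default) constant recombination. Real data add biased
gene conversion, mutation-rate and recombination-rate heterogeneity,
genotyping and phasing error, reference bias and accessibility artifacts.
Passing tests therefore demonstrate correctness of the implementation and
the method's behaviour under its own assumptions — not calibrated
performance on real genomes. Scan probabilities are not posterior
probabilities; candidate regions require independent validation.

## Known limitations

* The two-background approximation ignores distance-dependence of
  recombination escape within a window and coalescence among escaped
  lineages at intermediate frequencies; it was tuned against and agrees
  with the exact single-locus sweep coalescent at window scale, but is an
  approximation nonetheless.
* The adaptive-introgression demography is a stand-in, not a fitted model;
  its defaults are plausible for human/Neanderthal history but not
  calibrated.
* Multi-population neutral demographies, background selection,
  under-dominance and time-varying selection coefficients are out of scope.
* Probability calibration and selection-coefficient regression are not
  attempted.
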
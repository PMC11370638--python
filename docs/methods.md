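# Methods

This note documents the models, estimators and numerical choices behind
virokin, and what the synthetic-data generator does and does not emulate.

## Infection-kinetics estimators

All estimators operate on discrete time series sampled at the experimental
grid (default 0–120 h in 6 h steps).

**Latent period.** The interval (t_{k−1}, t_k] for the smallest k with
V_k ≥ 1.1·V_{k−1}. The "at least 10%" boundary is inclusive; a relative
slack of 10⁻¹² absorbs floating-point rounding at the boundary (1.1 · 100 is
not representable exactly). The rule is deliberately literal and therefore
noise-sensitive: an optional sustained-increase guard additionally requires
the next timepoint to be non-decreasing; it is off by default.

**Burst sizes.** B = (max S − baseline) / (peak H − post-peak min H), where S
is the virus-particle or genome-copy series. The baseline is the minimum of
S over [0, latent end] (falling back to S(t₀) when no latent end is found):
free virus commonly dips before the first burst because inoculated particles
adsorb to cells, and the pre-rise minimum is robust to that dip while
coinciding with S(t₀) on monotone data. The denominator is the host peak
minus the subsequent minimum — not H(t₀) minus the minimum — because hosts
keep growing between inoculation and lysis onset.

**Maximum production rate.** Ordinary least squares is fitted on every window
of at least `min_window_points` (default 3) consecutive timepoints; the
window with the largest slope is reported with its bounds and r². Ties (at
relative tolerance 10⁻⁹) are broken toward the earliest start, and among
windows with the same start toward the longest, so a globally linear series
reports the full series as its window. The host growth rate μ applies the
same scan to ln H(t) and converts to d⁻¹. Caveat: with the minimum window of
3 points, multiplicative measurement noise inflates the steepest window
(extreme-value selection over many windows); for noisy control series a
larger `min_window_points` (5–7) gives a much less biased μ.

## qPCR model

The standard curve is a least-squares line Cq = a·log₁₀(copies) + b fitted
to a dilution series with at least three distinct levels; amplification
efficiency is the standard E = 10^(−1/a) − 1 (a = −log₂10 ≈ −3.3219 gives
E = 100%). Quantification inverts the curve and multiplies by the plate
factor and any configured dilution factor. Technical replicates are averaged
on the Cq scale, since Cq is the measured quantity. Plates are harmonized
multiplicatively: the factor for plate k is the arithmetic mean over shared
internal standards of (reference-plate copies)/(plate-k copies); the
reference plate has factor 1. A geometric mean would be the natural
alternative if standards spanned orders of magnitude; with the narrow-range
standards this is designed for, the two coincide to well under a percent.

## Min-max normalization and percent-of-single

Genome-copy series from different primer pairs and experiments are made
comparable by mapping each replicate series through
x ↦ (x − ref_min)/(ref_max − ref_min), where ref_min and ref_max are the
means over the matching single-infection reference replicates of each
replicate's own minimum and maximum. References are scoped to the same
experiment and virus; values are not clipped, so suppression and overshoot
remain visible. Coinfection yields are summarised per replicate as a
percentage of the single-treatment mean (replicates are unpaired), reported
as mean ± sample sd.

## Gated group comparisons

Levene's test with mean centering (the classical form) at α = 0.05 routes
each comparison: homogeneous variances go to the parametric branch
(pooled-variance Student t for two groups, df = n₁+n₂−2; one-way ANOVA with
Tukey's HSD for three or more), heterogeneous to the rank branch (Wilcoxon
rank-sum, computed as the equivalent Mann–Whitney U, exact when sample sizes
permit; Kruskal–Wallis with Dunn's test, Holm-adjusted by default,
Bonferroni/BH configurable). All tests are two-sided. The pooled t is also
available directly from summary statistics (means, sds, ns). Compact letter
displays are built from the maximal cliques of the "not significantly
different" graph at the family-wise α, which guarantees that two groups
share a letter exactly when their adjusted p ≥ α.

Degenerate inputs are defined rather than erroring: identical constant
groups give t = 0, p = 1 (and F = 0 with a single letter); zero pooled
variance with unequal means gives an infinite statistic with p = 0.

A small-sample caveat: mean-centered Levene is anticonservative at n = 6 per
group (true size ≈ 7% at nominal 5%; at n = 30 it is accurate). The gated
two-group procedure as a whole nevertheless holds its size (empirically
≈ 0.048 at n = 6), because both branches are valid under either routing.

## Kinetic-class pipeline

Order of operations: (1) median-of-ratios size factors — per sample, the
median over genes detected in all samples of that gene's count divided by
its geometric mean across samples, with the median taken on the log scale
(geometric interpolation between middle genes, matching DESeq2); (2)
division of normalized counts by gene length; (3) replicate averaging per
timepoint; (4) per-gene centering and scaling using the sample sd (ddof = 1;
genes with zero variance get all-zero profiles and are flagged); (5) a
per-gene shift by the row minimum to restore non-negativity; (6) nonsmooth
NMF; (7) class assignment.

**nsNMF.** V ≈ W·S·H with smoothing matrix S = (1−θ)I + (θ/k)J (J all-ones,
column-stochastic), solved by alternating multiplicative Frobenius updates
in which the fixed effective factors are W·S (when updating H) and S·H (when
updating W); this keeps the objective non-increasing at every iteration. At
θ = 0, S is the exact identity and the algorithm is plain NMF. Defaults:
θ = 0.5, up to 2000 iterations, stop at relative objective decrease < 10⁻⁶,
30 random restarts keeping the best objective, all seeded through one root
generator. Inputs must be non-negative; a small ε = 10⁻¹² guards
denominators.

**Class assignment.** Each gene goes to the component with its largest basis
loading; components are ordered early → late by the peak timepoint of the
mean profile of their member genes (the coefficient row's peak covers empty
components), and named early/mid/late (k = 3) or early/early-mid/mid/late
(k = 4). Argmax ties are broken toward the temporally earlier class and the
genes flagged.

**Replicate concordance.** Before replicates are averaged, samples are
clustered by the argmax of their nsNMF coefficients with rank equal to the
number of timepoints. The input is size-factor-normalized,
length-standardized counts additionally scaled per gene by the gene's mean,
so that components capture relative temporal profiles rather than absolute
gene magnitudes — without this, an aberrant sample can hide inside a
large-magnitude component. The verdict passes when every replicate group
shares one cluster; discordant samples are named.

**Differential expression.** The module deliberately stops at the threshold
rule — significant iff |log₂FC| > 2 and adjusted p < 0.001, both strict —
applied to an externally supplied or simulator-generated table. Full
negative-binomial Wald inference is out of scope; a convenience log₂ fold
change on normalized counts with pseudocount 1 is provided.

## The coinfection simulator

No mechanistic model of prasinovirus superinfection interference exists;
the simulator is a phenomenological stage-structured compartment model whose
purpose is to give every estimator exact ground truth and to reproduce the
dominance/delay/temperature phenomena qualitatively. It is a test harness,
not a scientific claim about mechanism.

**Dynamics.** Susceptible hosts S grow at μ/24 h⁻¹ (μ defaults: 0.39 d⁻¹ at
3 °C, 0.56 d⁻¹ at 7 °C). Each virus v has adsorption coefficient φ_v
(default 5·10⁻⁷ ml h⁻¹), and infective free virus infects susceptibles at
φ_v·V_inf·S. Infected cells traverse m Erlang stages whose total mean is the
latent period L (default 21 h at 3 °C); at the chain's end they lyse,
releasing `burst` particles (fraction f_inf infective) and `genome_burst`
copies (default equal to the particle burst). Inoculation is an impulse of
va_ratio·H₀ particles (v:a default 10, H₀ = 2·10⁵ cells ml⁻¹) at each
virus's add time. Burst defaults are 172 (virus A, ~40% infective) and 226
(virus B, ~60% infective), mirroring the experimental system.

Two deliberate idealizations give the estimators exact truth: infected cells
neither grow nor adsorb homologous virus (receptor saturation), so free
virus is flat between the end of the adsorption dip and lysis onset and the
max-increase burst estimator is exact; and genome copies appear in the
medium only at lysis (no intracellular replication signal), so the genome
yield per lysed cell is exactly the configured value.

**Coinfection and protection.** Infected cells remain adsorptive to the
heterologous virus. A single-infected cell at stage j is converted to the
coinfected class only while its stage age j·L/m is below
`protection_time_h` (default 12 h); later superinfection leaves the primary
yield intact and the adsorbed virion is lost. A coinfected cell continues on
its primary clock and at lysis releases each virus's yield scaled by that
virus's output share ρ_v ∈ [0, 1] (defaults ρ_A = 0.65, ρ_B = 0.21, the
study system's point estimates). The stage-age proxy for protection is one
of several phenomenologies consistent with delayed-superinfection behaviour
and is the model's most arbitrary ingredient.

**Latent-stage count.** The Erlang shape defaults to m = 400, making lysis
onset near-deterministic. This is required by the latent-period operational
definition: with ~200-fold per-cell amplification, even 0.5% early lysis
triggers the 10% rise rule, so a broad latent distribution (small m) would
put the detected latent interval many hours before the mean latent period.
The infection-time spread (mean ~2.5 h at the default adsorption rate) still
smooths lysis over several hours.

**Temperature.** Temperature acts through μ and through per-virus
multiplicative modifiers on the latent rate 1/L and genome production
(defaults at 7 °C shorten L to ~15 h for virus A and ~9 h for virus B,
matching the qualitative ordering observed experimentally).

**Integration.** Fixed-step RK4 with dt = 0.05 h, capped at 1/(max stage
rate) so the stiff stage cascade stays inside the stability region at high
temperature; states are clamped at 0 after each step; inoculation events
split the integration exactly. Fixed stepping was chosen over adaptive
integration for bit-reproducibility across runs and platforms. Mass balance
(cumulative copies released per class = per-class yield × cumulative lysed
cells) holds to ~10⁻¹⁵ relative and is asserted in tests at 10⁻³.

**Observation model.** Multiplicative lognormal noise with mean 1 and
configurable CV (default 5%) on flow-cytometry counts; genome copies get the
same noise, a detection floor (10³ copies ml⁻¹), and are then routed through
the forward standard curve (with per-plate bias) and inverted by the
quantification code, exercising the same path real Cq data takes.
Everything is deterministic given a seed.

**Expression generator.** Gene means follow class-specific temporal shapes
on the RNA grid (0, 6, 12, 18, 24, 30 h), scaled by a lognormal per-gene
base level, gene length per kb, and a lognormal per-sample depth factor;
counts are negative-binomial with var = m + α·m² (default α = 0.1; α = 0
gives Poisson). Genes with planted log₂ fold changes shift by 2^lfc in the
non-reference condition. The default class shapes are expressed relative to
the median gene's trajectory — the gauge in which median-of-ratios
normalization works, since any common per-column factor is removed by it;
shapes outside that gauge would be warped by normalization into each other
(with every gene temporally regulated there is no stable majority, so size
factors absorb the median trajectory). The truth table reports the planted
fold change alongside an estimated log₂FC from pooled normalized means
(pseudocount 1) and a BH-adjusted p from a per-gene paired t on log₂ counts
matched by timepoint and replicate — a lightweight stand-in for count-model
inference, adequate for threshold-rule studies at the simulated depths.

## What the simulator does not emulate

Diel light–dark forcing (a flag is reserved), intracellular genome
replication before lysis, re-adsorption of progeny to infected cells,
defective particles beyond a fixed non-infective fraction, plate-to-plate
qPCR efficiency differences (only multiplicative bias), overdispersed or
count-based flow-cytometry noise, and any mechanistic basis for the
interference shares ρ. Passing recovery tests therefore demonstrates that
the estimators are correct under the model's assumptions and robust to
multiplicative noise — not that real coinfection data meet those
assumptions.

## Problem sizes

The test suite and acceptance script use: 21-point time grids (0–120 h,
6 h); 100 noisy-observation seeds for burst recovery; 50 seeds × 3
replicates for the coinfection yield percentages; 10 000 simulations for the
type-I calibration of the gated procedure; 20 seeds × 50 genes/class at NB
dispersion 0.1 for kinetic-class recovery at ranks 3 and 4 with 30 nsNMF
restarts. These sizes give Monte-Carlo standard errors comfortably below
the tolerances asserted on each quantity.

## Known limitations

- The latent-period rule reports grid intervals, so its resolution is the
  sampling interval; it cannot localize lysis onset within a 6 h gap.
- Single-replicate burst estimates at 5% multiplicative noise carry a ~+5%
  bias (the numerator takes a maximum over many noisy timepoints); the bias
  shrinks with replicate averaging but does not vanish.
- nsNMF class recovery at rank 4 is limited by the genuine temporal overlap
  of early and early-mid genes; a few percent of genes near the class
  boundary are interchangeable even at moderate noise.
- Dunn's test uses the normal approximation with tie correction; for very
  small groups with heavy ties an exact permutation approach would be
  preferable.
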
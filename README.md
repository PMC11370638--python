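# virokin

Analysis toolkit for one-step virus infection experiments in microalgal
host–virus systems, built around virus–virus coinfection (superinfection)
studies in the Arctic picoalga *Micromonas polaris* and its dsDNA
prasinoviruses. It covers the quantitative pipeline such experiments need —
from flow-cytometry and qPCR time series to viral gene-expression
clustering — together with a mechanistically explicit synthetic-data
simulator that provides exact ground truth for every estimator.

## What it computes

Given time series of host cells H(t), free virus particles V(t) (flow
cytometry) and viral genome copies G(t) (*polB* qPCR, one copy per genome):

- **Latent period** — the interval (t_{k−1}, t_k] ending at the first
  timepoint with V_k ≥ 1.1·V_{k−1} (a rise of at least 10%).
- **Burst sizes** — particles (B_p) or genome copies (B_g) produced per lysed
  host cell: the maximum increase in V (or G) over its pre-rise baseline,
  divided by the maximum decline in H (peak minus post-peak minimum).
- **Maximum production rates** — the steepest OLS slope over all windows of ≥3
  consecutive timepoints; host growth rate μ (d⁻¹) from the same scan on
  ln H(t).
- **qPCR quantification** — standard-curve fit Cq = a·log₁₀(copies) + b with
  amplification efficiency E = 10^(−1/a) − 1, inversion of Cq values to
  copies ml⁻¹, and multiplicative plate harmonization from shared internal
  standards.
- **Min-max normalization** — each genome-copy series rescaled to the averaged
  extrema of the matching single-infection reference, and coinfection yields
  expressed as percent of the single-infection mean.
- **Gated statistics** — Levene's test (α = 0.05) routes comparisons to
  Student's pooled t / one-way ANOVA + Tukey HSD, or to Wilcoxon rank-sum /
  Kruskal–Wallis + Dunn, with compact letter displays at family-wise
  error < 0.05.
- **Kinetic classes** — median-of-ratios size factors, gene-length
  standardization, per-timepoint replicate averaging with per-gene
  centering/scaling, then nonsmooth NMF (V ≈ W·S·H with
  S = (1−θ)I + (θ/k)·J) to cluster viral genes into early → late temporal
  classes; plus replicate-concordance checks and the |log₂FC| > 2,
  P-adj < 0.001 differential-expression rule.
- **Simulation** — a stage-structured host–virus ODE model with Erlang latent
  periods, configurable burst sizes, dual-infection interference (per-virus
  coinfection output shares ρ), delayed secondary inoculation with an
  age-dependent protection window, temperature scaling, lognormal
  flow-cytometry/qPCR observation noise routed through the forward standard
  curve, and negative-binomial RNA counts with planted kinetic classes and
  fold changes.

## Worked example

```python
import numpy as np
from virokin import (
    SimulationConfig, VirusParams, InterferenceParams, ObservationModel,
    simulate_infection, observe, detect_latent_period, particle_burst_size,
    genome_burst_size, percent_of_single, compare_two_from_summary,
)

va = VirusParams(name="A", burst=172.0, infective_fraction=0.4)   # MpoV-45T-like
vb = VirusParams(name="B", burst=226.0, infective_fraction=0.6)   # MpoV-46T-like
inter = InterferenceParams(output_share={"A": 0.65, "B": 0.21})

dual = simulate_infection(SimulationConfig(viruses=(va, vb)), inter)
single_b = simulate_infection(SimulationConfig(viruses=(vb,)), inter)

obs = ObservationModel(fcm_cv=0.05, qpcr_cv=0.05)
t_dual = observe(dual, obs, treatment="dual", seed=1)
t_single = observe(single_b, obs, treatment="single_B", seed=2)

fr = single_b.frame  # noise-free trajectory
t, v, h = fr["time_h"].to_numpy(), fr["V_B"].to_numpy(), fr["H"].to_numpy()
lat = detect_latent_period(t, v)
print(f"latent period: ({lat.t_start:g}, {lat.t_end:g}] h")
print(f"particle burst size: {particle_burst_size(t, v, t, h):.0f} per lysed cell")

def genome_bursts(table, treatment):
    out = []
    for rep in table.replicates(treatment, "genome_copies_B"):
        t, g = table.series(treatment, rep, "genome_copies_B")
        _, h = table.series(treatment, rep, "host_cells")
        out.append(genome_burst_size(t, g, t, h))
    return out

mean_pct, sd_pct = percent_of_single(
    genome_bursts(t_dual, "dual"), genome_bursts(t_single, "single_B")
)
print(f"virus B genome yield in coinfection: {mean_pct:.0f} +/- {sd_pct:.0f}% of single infection")

res = compare_two_from_summary(172.0, 19.0, 6, 226.0, 31.0, 6)
print(f"burst-size difference: t({res.df}) = {res.statistic:.1f}, P = {res.p_value:.3f}")
```

Output:

```
latent period: (18, 24] h
particle burst size: 226 per lysed cell
virus B genome yield in coinfection: 21 +/- 1% of single infection
burst-size difference: t(10) = -3.6, P = 0.005
```

The simulated single infection shows an 18–24 h latent period and returns the
configured burst size of 226 particles per lysed cell. In the dual infection
the suppressed virus realizes only ~21% of its single-infection genome yield
— the planted interference share recovered through the noisy qPCR
observation and estimation pipeline. The final line is the pooled two-sample
t-test comparing the two viruses' particle burst sizes from their summary
statistics (means 172 vs 226, sds 19 vs 31, n = 6 each).

A command-line interface mirrors the main steps; see `virokin --help`
(subcommands `simulate`, `kinetics`, `normalize`, `compare`, `classes`).

## Layout

- `src/virokin/io.py` — series tables, validation, qPCR calibration
- `src/virokin/kinetics.py` — latent period, burst sizes, production rates
- `src/virokin/normalize.py` — min-max normalization, percent-of-single
- `src/virokin/grouptests.py` — variance-gated tests, post hoc letters
- `src/virokin/kinetic_classes.py` — size factors, nsNMF, class assignment
- `src/virokin/simdata.py` — coinfection simulator and observation models
- `src/virokin/cli.py` — thin command-line wrapper
- `docs/methods.md` — model description, assumptions and design choices
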
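"""Synthetic coinfection experiments: dynamics, observation noise, RNA counts.

A phenomenological stage-structured host-virus model stands in for the wet
experiments so every estimator in the package has exact ground truth:

* susceptible hosts grow exponentially (mu, d^-1) and are infected by free
  infective virus at rate phi * V_inf * S;
* infected cells pass through m Erlang latent stages (total mean latent
  period L hours) and lyse, releasing ``burst`` particles (a fraction f_inf
  of them infective) and ``genome_burst`` genome copies per cell;
* an infected cell can be superinfected by the heterologous virus while its
  latent-stage age is below ``protection_time_h``; a coinfected cell releases
  each virus's yield scaled by that virus's output share rho (mutual
  interference), while later superinfection leaves the primary yield intact;
* a second virus may be inoculated with a delay, and temperature scales the
  host growth rate, the latent rate 1/L, and genome production.

The observation layer adds multiplicative lognormal noise to flow-cytometry
counts, routes genome copies through a forward qPCR standard curve (so the
quantification code can invert them), and draws negative-binomial RNA counts
with planted kinetic classes and condition fold-changes.

The model is a test harness: integration is fixed-step RK4 (0.05 h) for
bit-reproducibility, and cells stop growing and stop adsorbing homologous
virus once infected, which keeps free-virus counts flat between adsorption
and lysis so burst-size ground truth is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    QpcrCalibration,
    SeriesTable,
    amplification_efficiency,
    copies_to_cq,
    cq_to_copies,
)
from .kinetic_classes import ExpressionMatrix

__all__ = [
    "VirusParams",
    "InterferenceParams",
    "SimulationConfig",
    "ObservationModel",
    "Trajectories",
    "simulate_infection",
    "observe",
    "scenario_suite",
    "default_class_profiles",
    "simulate_expression",
    "DEFAULT_MU_BY_TEMP",
]

#: host growth rate (d^-1) by culture temperature (degC)
DEFAULT_MU_BY_TEMP = {3.0: 0.39, 7.0: 0.56}

RNA_TIMEPOINTS = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0)


@dataclass(frozen=True)
class VirusParams:
    """Per-virus life-history parameters for the infection model."""

    name: str  # "A" or "B"
    burst: float  # particles released per lysed cell
    infective_fraction: float  # f_inf of released / inoculated particles
    genome_burst: float | None = None  # copies per lysed cell (defaults to burst)
    adsorption: float = 5e-7  # phi, ml h^-1
    latent_h: float = 21.0  # mean latent period L (hours)
    latent_stages: int = 400  # Erlang shape m; near-deterministic latent
    va_ratio: float = 10.0  # inoculated particles per initial host cell
    add_time_h: float = 0.0  # inoculation delay

    def __post_init__(self) -> None:
        if self.name not in ("A", "B"):
            raise ValueError("virus name must be 'A' or 'B'")
        if self.latent_stages < 1:
            raise ValueError("latent_stages must be >= 1")
        for f, v in [
            ("burst", self.burst),
            ("adsorption", self.adsorption),
            ("latent_h", self.latent_h),
            ("va_ratio", self.va_ratio),
            ("add_time_h", self.add_time_h),
        ]:
            if v < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 < self.infective_fraction <= 1:
            raise ValueError("infective_fraction must be in (0, 1]")

    @property
    def genome_burst_eff(self) -> float:
        return self.burst if self.genome_burst is None else self.genome_burst


def _default_viruses() -> tuple[VirusParams, VirusParams]:
    # study defaults: virus A (MpoV-45T-like) burst 172, ~40% infective;
    # virus B (MpoV-46T-like) burst 226, ~60% infective
    return (
        VirusParams(name="A", burst=172.0, infective_fraction=0.4),
        VirusParams(name="B", burst=226.0, infective_fraction=0.6),
    )


@dataclass(frozen=True)
class InterferenceParams:
    """Phenomenological coinfection interference.

    ``output_share`` gives, per virus, the fraction of its single-infection
    yield realized in a coinfected cell (study point estimates: 0.65 for the
    dominant virus A, 0.21 for the suppressed virus B).  A cell whose latent
    age exceeds ``protection_time_h`` when the second virus arrives keeps its
    full primary yield and the superinfecting virion is lost.
    ``temperature_modifiers`` maps temperature (degC) -> virus name ->
    multiplicative factors on the latent rate (1/L) and genome production.
    """

    output_share: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.65, "B": 0.21}
    )
    protection_time_h: float = 12.0
    temperature_modifiers: Mapping[float, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {
            7.0: {
                "A": {"latent_rate": 21.0 / 15.0, "genome": 1.0},
                "B": {"latent_rate": 21.0 / 9.0, "genome": 1.0},
            }
        }
    )

    def __post_init__(self) -> None:
        for v, rho in self.output_share.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"output share for {v} must be in [0, 1]")
        if self.protection_time_h < 0:
            raise ValueError("protection_time_h must be >= 0")

    def modifier(self, temperature_c: float, virus: str, key: str) -> float:
        return (
            self.temperature_modifiers.get(temperature_c, {})
            .get(virus, {})
            .get(key, 1.0)
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment-level configuration of a one-step infection run."""

    h0: float = 2e5  # initial host density, cells ml^-1
    temperature_c: float = 3.0
    mu: float | None = None  # host growth rate d^-1; default by temperature
    t_grid: tuple[float, ...] = tuple(np.arange(0.0, 121.0, 6.0))
    dt: float = 0.05  # RK4 step (h)
    viruses: tuple[VirusParams, ...] = field(default_factory=_default_viruses)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")
        t = np.asarray(self.t_grid, float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing with >= 2 points")
        if not 1 <= len(self.viruses) <= 2:
            raise ValueError("one or two viruses supported")
        names = [v.name for v in self.viruses]
        if len(set(names)) != len(names):
            raise ValueError("virus names must be distinct")

    @property
    def mu_effective(self) -> float:
        if self.mu is not None:
            return self.mu
        return DEFAULT_MU_BY_TEMP.get(self.temperature_c, 0.39)


@dataclass
class Trajectories:
    """Noise-free model output on the sampling grid plus ground truth."""

    frame: pd.DataFrame  # columns: time_h, H, V_A, V_B, G_A, G_B
    truth: dict
    config: SimulationConfig
    interference: InterferenceParams


def simulate_infection(
    config: SimulationConfig,
    interference: InterferenceParams | None = None,
) -> Trajectories:
    """Deterministic stage-structured coinfection dynamics on ``config.t_grid``.

    Returns host cells (intact, infected or not), free virus particles and
    released genome copies per virus, plus a ground-truth ledger of lysed
    cells and produced particles/copies per infection class (used for the
    mass-balance invariant and estimator calibration).
    """
    inter = interference if interference is not None else InterferenceParams()
    viruses = {v.name: v for v in config.viruses}
    temp = config.temperature_c
    mu_h = config.mu_effective / 24.0

    # resolve both virus slots; an absent virus gets zero inoculum
    defaults = {v.name: v for v in _default_viruses()}
    va = viruses.get("A", defaults["A"])
    vb = viruses.get("B", defaults["B"])
    present = {"A": "A" in viruses, "B": "B" in viruses}

    m_a, m_b = va.latent_stages, vb.latent_stages
    rate_a = m_a / va.latent_h * inter.modifier(temp, "A", "latent_rate")
    rate_b = m_b / vb.latent_h * inter.modifier(temp, "B", "latent_rate")
    g_a = va.genome_burst_eff * inter.modifier(temp, "A", "genome")
    g_b = vb.genome_burst_eff * inter.modifier(temp, "B", "genome")
    rho_a = inter.output_share.get("A", 1.0)
    rho_b = inter.output_share.get("B", 1.0)
    # latent-stage index below which a cell is still superinfectable
    elig_a = int(
        np.searchsorted(
            np.arange(m_a) * (1.0 / rate_a), inter.protection_time_h, side="left"
        )
    )
    elig_b = int(
        np.searchsorted(
            np.arange(m_b) * (1.0 / rate_b), inter.protection_time_h, side="left"
        )
    )

    # state layout
    i0 = 1
    sl_ia = slice(i0, i0 + m_a)
    sl_ib = slice(sl_ia.stop, sl_ia.stop + m_b)
    sl_ca = slice(sl_ib.stop, sl_ib.stop + m_a)
    sl_cb = slice(sl_ca.stop, sl_ca.stop + m_b)
    n_cells = sl_cb.stop
    (
        i_vat, i_vai, i_vbt, i_vbi, i_ga, i_gb,
        i_lys_a, i_lys_b, i_lys_ca, i_lys_cb,
        i_ga_s, i_ga_c, i_gb_s, i_gb_c, i_va_p, i_vb_p,
    ) = range(n_cells, n_cells + 16)
    n_state = n_cells + 16

    def deriv(y: np.ndarray) -> np.ndarray:
        d = np.zeros(n_state)
        s = y[0]
        ia, ib = y[sl_ia], y[sl_ib]
        ca, cb = y[sl_ca], y[sl_cb]
        vat, vai, vbt, vbi = y[i_vat], y[i_vai], y[i_vbt], y[i_vbi]

        d[0] = mu_h * s
        lam_a = va.adsorption * vai * s
        lam_b = vb.adsorption * vbi * s
        d[0] -= lam_a + lam_b
        # all particles (infective or not) adsorb to susceptible cells
        d[i_vat] -= va.adsorption * vat * s
        d[i_vai] -= lam_a
        d[i_vbt] -= vb.adsorption * vbt * s
        d[i_vbi] -= lam_b

        dia = np.zeros(m_a)
        dib = np.zeros(m_b)
        dca = np.zeros(m_a)
        dcb = np.zeros(m_b)
        dia[0] += lam_a
        dib[0] += lam_b

        flow_ia = rate_a * ia
        dia -= flow_ia
        dia[1:] += flow_ia[:-1]
        lys_a = flow_ia[-1]

        flow_ib = rate_b * ib
        dib -= flow_ib
        dib[1:] += flow_ib[:-1]
        lys_b = flow_ib[-1]

        # heterologous superinfection of young single-infected cells
        if present["A"] and present["B"]:
            conv_a = vb.adsorption * vbi * ia[:elig_a]
            dia[:elig_a] -= conv_a
            dca[:elig_a] += conv_a
            loss = conv_a.sum()
            d[i_vbi] -= loss
            d[i_vbt] -= loss

            conv_b = va.adsorption * vai * ib[:elig_b]
            dib[:elig_b] -= conv_b
            dcb[:elig_b] += conv_b
            loss = conv_b.sum()
            d[i_vai] -= loss
            d[i_vat] -= loss

        flow_ca = rate_a * ca
        dca -= flow_ca
        dca[1:] += flow_ca[:-1]
        lys_ca = flow_ca[-1]

        flow_cb = rate_b * cb
        dcb -= flow_cb
        dcb[1:] += flow_cb[:-1]
        lys_cb = flow_cb[-1]

        d[sl_ia] += dia
        d[sl_ib] += dib
        d[sl_ca] += dca
        d[sl_cb] += dcb

        lys_co = lys_ca + lys_cb
        # single-infection releases
        d[i_vat] += va.burst * lys_a
        d[i_vai] += va.infective_fraction * va.burst * lys_a
        d[i_ga] += g_a * lys_a
        d[i_vbt] += vb.burst * lys_b
        d[i_vbi] += vb.infective_fraction * vb.burst * lys_b
        d[i_gb] += g_b * lys_b
        # coinfected cells release both viruses, each scaled by its share
        d[i_vat] += rho_a * va.burst * lys_co
        d[i_vai] += va.infective_fraction * rho_a * va.burst * lys_co
        d[i_ga] += rho_a * g_a * lys_co
        d[i_vbt] += rho_b * vb.burst * lys_co
        d[i_vbi] += vb.infective_fraction * rho_b * vb.burst * lys_co
        d[i_gb] += rho_b * g_b * lys_co

        # ground-truth ledgers
        d[i_lys_a] = lys_a
        d[i_lys_b] = lys_b
        d[i_lys_ca] = lys_ca
        d[i_lys_cb] = lys_cb
        d[i_ga_s] = g_a * lys_a
        d[i_ga_c] = rho_a * g_a * lys_co
        d[i_gb_s] = g_b * lys_b
        d[i_gb_c] = rho_b * g_b * lys_co
        d[i_va_p] = va.burst * lys_a + rho_a * va.burst * lys_co
        d[i_vb_p] = vb.burst * lys_b + rho_b * vb.burst * lys_co
        return d

    y = np.zeros(n_state)
    y[0] = config.h0

    events = sorted(
        {v.add_time_h for name, v in (("A", va), ("B", vb)) if present[name]}
    )
    t_grid = np.asarray(config.t_grid, float)
    t_end = float(t_grid[-1])
    breakpoints = sorted(set([0.0, t_end] + [e for e in events if 0.0 <= e <= t_end]))

    def inoculate(t: float) -> None:
        for name, v in (("A", va), ("B", vb)):
            if present[name] and math.isclose(v.add_time_h, t, abs_tol=1e-9):
                dose = v.va_ratio * config.h0
                if name == "A":
                    y[i_vat] += dose
                    y[i_vai] += v.infective_fraction * dose
                else:
                    y[i_vbt] += dose
                    y[i_vbi] += v.infective_fraction * dose

    records = np.zeros((t_grid.size, 6))
    rec_i = 0

    def record(t: float) -> None:
        nonlocal rec_i
        while rec_i < t_grid.size and t_grid[rec_i] <= t + 1e-9:
            h_total = y[0] + y[sl_ia].sum() + y[sl_ib].sum() + y[sl_ca].sum() + y[sl_cb].sum()
            records[rec_i] = [
                t_grid[rec_i], h_total, y[i_vat], y[i_vbt], y[i_ga], y[i_gb]
            ]
            rec_i += 1

    # cap the step so dt * (fastest stage rate) stays well inside the RK4
    # stability region even for temperature-shortened latent periods
    dt = min(config.dt, 1.0 / max(rate_a, rate_b))
    t = 0.0
    inoculate(0.0)
    record(0.0)
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        if seg_start > 0.0:
            inoculate(seg_start)
        t = seg_start
        n_steps = int(round((seg_end - seg_start) / dt))
        step = (seg_end - seg_start) / max(n_steps, 1)
        for _ in range(max(n_steps, 1)):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * step * k1)
            k3 = deriv(y + 0.5 * step * k2)
            k4 = deriv(y + step * k3)
            y += (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.maximum(y, 0.0, out=y)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError("unstable integration step")
            t += step
            record(t)

    frame = pd.DataFrame(records, columns=["time_h", "H", "V_A", "V_B", "G_A", "G_B"])
    lys_co = y[i_lys_ca] + y[i_lys_cb]
    truth = {
        "lysed_single_A": y[i_lys_a],
        "lysed_single_B": y[i_lys_b],
        "lysed_coinfected": lys_co,
        "lysed_total": y[i_lys_a] + y[i_lys_b] + lys_co,
        "genome_produced_A_single": y[i_ga_s],
        "genome_produced_A_coinfected": y[i_ga_c],
        "genome_produced_B_single": y[i_gb_s],
        "genome_produced_B_coinfected": y[i_gb_c],
        "particles_produced_A": y[i_va_p],
        "particles_produced_B": y[i_vb_p],
        "genome_yield_A": g_a,
        "genome_yield_B": g_b,
        "output_share": {"A": rho_a, "B": rho_b},
        "burst": {"A": va.burst, "B": vb.burst},
        "latent_h": {"A": m_a / rate_a, "B": m_b / rate_b},
        "viruses_present": [n for n in ("A", "B") if present[n]],
    }
    return Trajectories(frame, truth, config, inter)


# --------------------------------------------------------------------------
# observation models
# --------------------------------------------------------------------------


def _ideal_calibration() -> QpcrCalibration:
    slope = -1.0 / math.log10(2.0)  # 100% efficiency
    return QpcrCalibration(
        slope=slope,
        intercept=38.0,
        efficiency=amplification_efficiency(slope),
        r_squared=1.0,
        plate_factors={"plate1": 1.0},
    )


@dataclass(frozen=True)
class ObservationModel:
    """Measurement layer: lognormal noise plus the qPCR forward model.

    ``fcm_cv``/``qpcr_cv`` are coefficients of variation of mean-one
    multiplicative lognormal noise; genome copies below ``qpcr_floor``
    (copies ml^-1) report at the floor (detection limit); ``nb_dispersion``
    is the negative-binomial dispersion alpha for RNA counts.
    """

    fcm_cv: float = 0.05
    qpcr_cv: float = 0.05
    qpcr_floor: float = 1e3
    plate_bias: Mapping[str, float] = field(default_factory=lambda: {"plate1": 1.0})
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fcm_cv < 0 or self.qpcr_cv < 0 or self.nb_dispersion < 0:
            raise ValueError("cvs and dispersion must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def observe(
    trajectories: Trajectories,
    observation: ObservationModel | None = None,
    treatment: str = "treatment",
    replicates: Sequence[str] = ("1", "2", "3"),
    calibration: QpcrCalibration | None = None,
    seed: int | None = None,
) -> SeriesTable:
    """Turn noise-free trajectories into a replicated, noisy SeriesTable.

    Flow-cytometry analytes get multiplicative lognormal noise; genome copies
    additionally pass through the forward qPCR standard curve (with plate
    bias) and are inverted back by the quantification code, exercising the
    same path real Cq data takes.  Deterministic given the seed.
    """
    obs = observation if observation is not None else ObservationModel()
    rng = np.random.default_rng(obs.seed if seed is None else seed)
    calib = calibration if calibration is not None else _ideal_calibration()
    plate = next(iter(obs.plate_bias))
    bias = obs.plate_bias[plate]
    calib = calib.with_plate_factors({plate: 1.0 / bias})

    fr = trajectories.frame
    present = trajectories.truth["viruses_present"]
    v_total = np.zeros(len(fr))
    if "A" in present:
        v_total = v_total + fr["V_A"].to_numpy()
    if "B" in present:
        v_total = v_total + fr["V_B"].to_numpy()

    analytes = {"host_cells": fr["H"].to_numpy()}
    if present:
        analytes["virus_particles"] = v_total
    if "A" in present:
        analytes["genome_copies_A"] = fr["G_A"].to_numpy()
    if "B" in present:
        analytes["genome_copies_B"] = fr["G_B"].to_numpy()

    t = fr["time_h"].to_numpy()
    rows = []
    for rep in replicates:
        for analyte, values in analytes.items():
            if analyte.startswith("genome"):
                noisy = np.maximum(
                    values * _lognormal_factors(rng, obs.qpcr_cv, len(values)),
                    obs.qpcr_floor,
                )
                # forward curve with plate bias, then standard inversion
                measured = [
                    cq_to_copies(copies_to_cq(c * bias, calib), calib, plate)
                    for c in noisy
                ]
            else:
                measured = values * _lognormal_factors(rng, obs.fcm_cv, len(values))
            for ti, vi in zip(t, measured):
                rows.append(
                    {
                        "time_h": ti,
                        "treatment": treatment,
                        "replicate": rep,
                        "analyte": analyte,
                        "value": max(float(vi), 0.0),
                        "temperature_c": trajectories.config.temperature_c,
                    }
                )
    design = {
        treatment: {
            "viruses": list(present),
            "delays_h": {
                v.name: v.add_time_h for v in trajectories.config.viruses
            },
            "temperature_c": trajectories.config.temperature_c,
        }
    }
    return SeriesTable(pd.DataFrame(rows), design)


# --------------------------------------------------------------------------
# the scenario suite mirroring the experimental design
# --------------------------------------------------------------------------

DELAYS_H = (0.0, 6.0, 12.0, 18.0, 24.0)


def _treatment_config(
    base: SimulationConfig, treatment: str
) -> SimulationConfig | None:
    va, vb = _default_viruses()
    if treatment == "single_A":
        return replace(base, viruses=(va,))
    if treatment == "single_B":
        return replace(base, viruses=(vb,))
    if treatment == "dual":
        return replace(base, viruses=(va, vb))
    if treatment.startswith("dual_delay_"):
        delay = float(treatment.removeprefix("dual_delay_"))
        return replace(base, viruses=(replace(va, add_time_h=delay), vb))
    return None


def scenario_suite(
    seed: int = 0,
    temperatures: Sequence[float] = (3.0, 7.0),
    n_replicates: int = 3,
    observation: ObservationModel | None = None,
    interference: InterferenceParams | None = None,
    t_grid: Sequence[float] | None = None,
) -> dict[float, SeriesTable]:
    """The full experimental design as noisy SeriesTables, one per temperature.

    Nine treatments each: an uninfected control, the two single infections,
    the simultaneous dual infection, and dual infections with the secondary
    virus (A) delayed by 0, 6, 12, 18 and 24 h; triplicate replicates on a
    0-120 h grid.
    """
    obs = observation if observation is not None else ObservationModel()
    inter = interference if interference is not None else InterferenceParams()
    treatments = ["control", "single_A", "single_B", "dual"] + [
        f"dual_delay_{int(d)}" for d in DELAYS_H
    ]
    rng = np.random.default_rng(seed)
    out: dict[float, SeriesTable] = {}
    for temp in temperatures:
        base = SimulationConfig(
            temperature_c=temp,
            t_grid=tuple(t_grid) if t_grid is not None else tuple(np.arange(0.0, 121.0, 6.0)),
        )
        frames = []
        design: dict[str, dict] = {}
        for treatment in treatments:
            if treatment == "control":
                traj = _simulate_control(base, inter)
            else:
                cfg = _treatment_config(base, treatment)
                assert cfg is not None
                traj = simulate_infection(cfg, inter)
            table = observe(
                traj,
                obs,
                treatment=treatment,
                replicates=[str(i + 1) for i in range(n_replicates)],
                seed=int(rng.integers(2**31)),
            )
            frames.append(table.data)
            design.update(table.design)
        out[temp] = SeriesTable(pd.concat(frames, ignore_index=True), design)
    return out


def _simulate_control(
    base: SimulationConfig, inter: InterferenceParams
) -> Trajectories:
    """Uninfected control: pure exponential host growth on the same grid."""
    va, vb = _default_viruses()
    cfg = replace(
        base,
        viruses=(
            replace(va, va_ratio=0.0),
            replace(vb, va_ratio=0.0),
        ),
    )
    traj = simulate_infection(cfg, inter)
    traj.truth["viruses_present"] = []
    return traj


# --------------------------------------------------------------------------
# synthetic RNA counts with planted kinetic classes
# --------------------------------------------------------------------------


def default_class_profiles(rank: int) -> pd.DataFrame:
    """Canonical temporal mean-expression shapes on the RNA sampling grid.

    Shapes are expressed relative to the median gene's trajectory (the gauge
    that median-of-ratios library normalization works in, since any common
    per-sample factor is removed by it): early genes peak at inoculation and
    decay, early-mid at 6 h, mid at 12 h, late rise through 24-30 h.
    """
    shapes = {
        "early": [1.0, 0.18, 0.09, 0.04, 0.09, 0.12],
        "early-mid": [0.66, 1.0, 0.51, 0.19, 0.21, 0.20],
        "mid": [0.09, 0.24, 1.0, 0.54, 0.49, 0.41],
        "late": [0.02, 0.02, 0.07, 0.20, 0.73, 1.0],
    }
    try:
        names = {3: ["early", "mid", "late"], 4: ["early", "early-mid", "mid", "late"]}[rank]
    except KeyError:
        raise ValueError("default profiles defined for rank 3 or 4") from None
    return pd.DataFrame(
        {name: shapes[name] for name in names}, index=list(RNA_TIMEPOINTS)
    ).T


def simulate_expression(
    n_genes_per_class: int = 50,
    class_profiles: pd.DataFrame | None = None,
    rank: int = 3,
    log2fc_planted: Mapping[str, float] | None = None,
    nb_dispersion: float = 0.1,
    n_replicates: int = 2,
    conditions: Sequence[str] = ("single", "dual"),
    mean_expression: float = 500.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Negative-binomial gene x sample counts with planted temporal classes.

    Gene means follow its class's temporal profile, scaled by a lognormal
    per-gene base level, gene length (per kb) and a per-sample size factor;
    genes listed in ``log2fc_planted`` (gene id -> log2 fold change) shift by
    2**lfc in the non-reference condition.  Counts are NB with
    ``var = mu + alpha * mu**2``.

    Returns the ExpressionMatrix, the true class labels, and a truth/DE table
    with the planted fold change plus an estimated log2FC and BH-adjusted p
    from a per-gene Welch t-test on log2(size-factor-normalized counts + 1)
    between conditions.
    """
    rng = np.random.default_rng(seed)
    profiles = (
        class_profiles if class_profiles is not None else default_class_profiles(rank)
    )
    class_names = list(profiles.index)
    timepoints = [float(c) for c in profiles.columns]

    genes = []
    truth_class = []
    for cname in class_names:
        for i in range(n_genes_per_class):
            genes.append(f"{cname}_g{i + 1:03d}")
            truth_class.append(cname)
    truth = pd.Series(truth_class, index=genes, name="true_class")

    lengths = pd.Series(
        rng.integers(300, 3000, size=len(genes)).astype(float),
        index=genes,
        name="length_bp",
    )
    base = mean_expression * rng.lognormal(0.0, 0.5, size=len(genes))
    lfc = pd.Series(0.0, index=genes)
    if log2fc_planted:
        for g, v in log2fc_planted.items():
            lfc[g] = v

    sample_ids, meta_rows = [], []
    for cond in conditions:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                sid = f"{cond}_T{int(tp)}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample": sid, "timepoint_h": tp, "condition": cond, "replicate": str(rep)}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    true_sf = pd.Series(
        rng.lognormal(0.0, 0.15, size=len(sample_ids)), index=sample_ids
    )

    prof = profiles.to_numpy()
    class_idx = {c: i for i, c in enumerate(class_names)}
    tp_idx = {t: i for i, t in enumerate(timepoints)}
    counts = np.zeros((len(genes), len(sample_ids)), dtype=np.int64)
    ref_cond = conditions[0]
    for j, sid in enumerate(sample_ids):
        cond = meta.loc[sid, "condition"]
        tp = float(meta.loc[sid, "timepoint_h"])
        shape_vals = prof[:, tp_idx[tp]]
        mu = (
            base
            * np.array([shape_vals[class_idx[c]] for c in truth_class])
            * (lengths.to_numpy() / 1000.0)
            * true_sf[sid]
        )
        if cond != ref_cond:
            mu = mu * np.power(2.0, lfc.to_numpy())
        if nb_dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / nb_dispersion
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    em = ExpressionMatrix(counts_df, lengths, meta)

    # truth/DE table: estimated lfc and BH-adjusted Welch p between conditions
    from .kinetic_classes import size_factors as _sf

    sf = _sf(counts_df.clip(lower=0) + 1)  # +1 guard: a gene may drop to 0
    norm = counts_df / sf
    logn = np.log2(norm + 1.0)
    cond_of = meta["condition"]
    a_cols = [s for s in sample_ids if cond_of[s] == ref_cond]
    b_cols = [s for s in sample_ids if cond_of[s] != ref_cond]
    de = pd.DataFrame(index=counts_df.index)
    de["true_log2fc"] = lfc
    if b_cols:
        from scipy import stats as _st
        from statsmodels.stats.multitest import multipletests as _mt

        # pooled-mean ratio keeps the estimate near the planted fold change
        # even for genes whose expression is concentrated at few timepoints
        est_lfc = np.log2(norm[b_cols].mean(axis=1) + 1.0) - np.log2(
            norm[a_cols].mean(axis=1) + 1.0
        )
        # samples are generated timepoint- and replicate-matched across
        # conditions, so a paired t on log counts removes temporal variance
        tt = _st.ttest_rel(logn[b_cols], logn[a_cols], axis=1)
        pvals = np.nan_to_num(tt.pvalue, nan=1.0)
        de["log2fc"] = est_lfc
        de["p"] = pvals
        de["padj"] = _mt(pvals, method="fdr_bh")[1]
    return em, truth, de
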
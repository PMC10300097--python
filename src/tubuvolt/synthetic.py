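"""Synthetic voltammograms, GCD cycle trains and the embedded reference
tables.

Every downstream analyzer in this package can be exercised without any
instrument data: `synth_cv_trace` builds a triangular potential sweep with
Gaussian peaks on chosen sweep directions plus a capacitive baseline and
optional noise, `synth_gcd_profile` builds an ideal constant-current cycle
train with a configurable capacity-fade schedule, and `paper_fixture_tables`
exposes the published reference values (energetics table, transport table,
load polynomial, battery figures) as the single in-package source of those
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .battery import GCDProfile
from .cv_energetics import CVTrace
from .errors import ConfigurationError, ResolutionError
from .mc_engine import LoadPolynomial

__all__ = [
    "SynthPeak",
    "CVSynthParams",
    "GCDSynthParams",
    "PaperFixtures",
    "synth_cv_trace",
    "table1_fixture_traces",
    "synth_gcd_profile",
    "paper_fixture_tables",
]


class SynthPeak(BaseModel):
    """One Gaussian feature: centre (V), width (V, standard deviation),
    signed amplitude (A) and the sweep it sits on."""

    model_config = ConfigDict(frozen=True)

    center: float
    width: float = Field(gt=0)
    amplitude: float
    sweep: Literal["forward", "reverse"] = "forward"


class CVSynthParams(BaseModel):
    """Parameters of a synthetic voltammogram."""

    model_config = ConfigDict(frozen=True)

    scan_rate: float = Field(default=0.05, gt=0, description="V/s")
    vertices: tuple[float, float] = Field(default=(-1.0, 1.0))
    peaks: tuple[SynthPeak, ...] = ()
    capacitive_baseline: float = Field(default=0.5e-6, description="A")
    noise_sd: float = Field(default=0.0, ge=0, description="A")
    e_step: float = Field(default=0.002, gt=0, description="potential step, V")
    seed: int = 0

    @property
    def window(self) -> tuple[float, float]:
        lo, hi = self.vertices
        return (min(lo, hi), max(lo, hi))


class GCDSynthParams(BaseModel):
    """Parameters of a synthetic charge/discharge cycle train.

    ``fade_model='exponential-to-floor'`` decays the per-cycle capacity
    geometrically from ``Q0`` so that the final generated cycle lands exactly
    on ``Q_floor``; ``'none'`` keeps every cycle at ``Q0``.
    """

    model_config = ConfigDict(frozen=True)

    n_cycles: int = Field(default=100, ge=1)
    Q0: float = Field(default=63.2, gt=0, description="initial capacity, mAh/g")
    fade_model: Literal["none", "exponential-to-floor"] = "exponential-to-floor"
    Q_floor: float = Field(default=36.35, gt=0, description="terminal capacity, mAh/g")
    I: float = Field(default=1.0, gt=0, description="current magnitude, A")
    m: float = Field(default=0.5, gt=0, description="electroactive mass, g")
    V_window: tuple[float, float] = Field(default=(0.0, 0.214))
    sample_dt: float = Field(default=1.0, gt=0, description="s")
    seed: int = 0


def synth_cv_trace(p: CVSynthParams) -> CVTrace:
    """Deterministic-per-seed triangular sweep with Gaussian peaks.

    The capacitive baseline follows the sweep sign (+ on the forward, - on
    the reverse branch); each peak is added only on its assigned sweep.
    """
    lo, hi = p.window
    up = np.arange(lo, hi, p.e_step)
    down = np.arange(hi, lo, -p.e_step)
    potential = np.concatenate([up, down, [lo]])
    n_fwd = up.size  # samples strictly on the forward branch
    rng = np.random.default_rng(p.seed)
    current = np.where(np.arange(potential.size) < n_fwd, 1.0, -1.0) * p.capacitive_baseline
    forward_mask = np.arange(potential.size) < n_fwd
    for peak in p.peaks:
        if not (lo <= peak.center <= hi):
            raise ConfigurationError(
                f"peak centre {peak.center} outside window ({lo}, {hi})"
            )
        shape = peak.amplitude * np.exp(-((potential - peak.center) ** 2) / (2 * peak.width**2))
        mask = forward_mask if peak.sweep == "forward" else ~forward_mask
        current = current + np.where(mask, shape, 0.0)
    if p.noise_sd > 0:
        current = current + rng.normal(0.0, p.noise_sd, size=potential.size)
    return CVTrace(potential, current, p.scan_rate)


def table1_fixture_traces(noise_sd: float = 0.0, seed: int = 0) -> dict[float, CVTrace]:
    """Six noise-free voltammograms whose forward adsorption peak at +0.30 V
    carries exactly the published peak-current magnitude for each scan rate.

    Desorption (-0.30 V) and hydrogen-evolution (+0.05 V) features are added
    on the reverse sweep at fixed fractions of the adsorption amplitude so
    the traces exercise the full peak taxonomy.
    """
    fixtures = paper_fixture_tables()
    traces: dict[float, CVTrace] = {}
    for _, row in fixtures.table1.iterrows():
        amp = abs(row["ip_A"])
        params = CVSynthParams(
            scan_rate=row["scan_rate_Vps"],
            peaks=(
                SynthPeak(center=0.30, width=0.02, amplitude=amp, sweep="forward"),
                SynthPeak(center=-0.30, width=0.02, amplitude=-0.6 * amp, sweep="reverse"),
                SynthPeak(center=0.05, width=0.015, amplitude=-0.3 * amp, sweep="reverse"),
            ),
            noise_sd=noise_sd,
            seed=seed,
        )
        traces[float(row["scan_rate_Vps"])] = synth_cv_trace(params)
    return traces


def _cycle_capacities(p: GCDSynthParams) -> np.ndarray:
    k = np.arange(p.n_cycles, dtype=float)
    if p.fade_model == "none":
        return np.full(p.n_cycles, p.Q0)
    if p.Q_floor > p.Q0:
        raise ConfigurationError("Q_floor must not exceed Q0")
    if p.n_cycles == 1 or p.Q_floor == p.Q0:
        return np.full(p.n_cycles, p.Q0)
    tau = (p.n_cycles - 1) / np.log(p.Q0 / p.Q_floor)
    return p.Q0 * np.exp(-k / tau)


def synth_gcd_profile(p: GCDSynthParams) -> GCDProfile:
    """Ideal linear charge/discharge cycle train sampled at ``sample_dt``.

    Discharge durations are set so I*dt/m reproduces the fade schedule's
    capacity for each cycle; charge segments mirror the discharge duration.
    Segment endpoints are always included in the sample grid, so recovered
    durations are exact up to float precision.
    """
    capacities = _cycle_capacities(p)
    v_lo, v_hi = min(p.V_window), max(p.V_window)
    times, volts, currents, cycles = [], [], [], []
    t0 = 0.0
    for cycle, q in enumerate(capacities, start=1):
        dt = q * p.m * 3.6 / p.I  # mAh/g -> s at this current and mass
        if p.sample_dt > dt:
            raise ResolutionError(
                f"sample_dt={p.sample_dt}s exceeds the {dt:.3g}s segment of cycle {cycle}"
            )
        grid = np.arange(0.0, dt, p.sample_dt)
        if grid[-1] < dt:
            grid = np.append(grid, dt)
        # Charge ramp v_lo -> v_hi at +I, then discharge v_hi -> v_lo at -I.
        times.append(t0 + grid)
        volts.append(v_lo + (v_hi - v_lo) * grid / dt)
        currents.append(np.full(grid.size, p.I))
        cycles.append(np.full(grid.size, cycle, dtype=int))
        t0 += dt
        times.append(t0 + grid)
        volts.append(v_hi - (v_hi - v_lo) * grid / dt)
        currents.append(np.full(grid.size, -p.I))
        cycles.append(np.full(grid.size, cycle, dtype=int))
        t0 += dt
    return GCDProfile(
        np.concatenate(times),
        np.concatenate(volts),
        np.concatenate(currents),
        np.concatenate(cycles),
    )


@dataclass(frozen=True)
class PaperFixtures:
    """Published reference values, embedded once for regression tests.

    ``table1``: per-scan-rate energetics (signed peak currents in A, free
    energies in eV, charge-transfer resistance as tabulated, resistivity in
    Ohm m, conductivity in S/m). ``table2``: per-load K+ transport rows
    (D in cm^2/s, mu in cm^2/(V s)). ``eq16_coeffs``: the published cubic
    load-response of the dimerization energy. ``battery`` and ``averages``:
    scalar reference figures keyed by name.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    eq16_coeffs: LoadPolynomial
    battery: dict[str, float] = field(default_factory=dict)
    averages: dict[str, float] = field(default_factory=dict)


def paper_fixture_tables() -> PaperFixtures:
    """The embedded printed reference values (single source; SI-ish units)."""
    table1 = pd.DataFrame(
        {
            "scan_rate_Vps": [0.010, 0.020, 0.050, 0.100, 0.150, 0.200],
            "load_Mohm": [1.81, 2.21, 3.85, 5.13, 7.35, 8.00],
            "ip_A": [-5.52e-6, -9.07e-6, -13.0e-6, -19.5e-6, -20.4e-6, -25.0e-6],
            "dG_eV": [1.19, 1.17, 1.16, 1.15, 1.15, 1.15],
            "R_ct": [2.33, 1.42, 0.99, 0.66, 0.63, 0.51],
            "rho_ohm_m": [1162.96, 707.77, 493.81, 329.21, 314.68, 256.78],
            "sigma_S_m": [0.86e-3, 1.41e-3, 2.03e-3, 3.04e-3, 3.18e-3, 3.89e-3],
        }
    )
    table2 = pd.DataFrame(
        {
            "load_Mohm": [1.81, 2.21, 3.85, 5.13, 7.35, 8.00],
            "ip_A": [-5.52e-6, -9.07e-6, -13.0e-6, -19.5e-6, -20.4e-6, -25.0e-6],
            "scan_rate_Vps": [0.010, 0.020, 0.050, 0.100, 0.150, 0.200],
            "D_cm2_s": [1.76e-7, 2.38e-7, 1.96e-7, 2.20e-7, 1.61e-7, 1.80e-7],
            "mu_cm2_Vs": [6.97e-6, 9.43e-6, 7.76e-6, 8.71e-6, 6.38e-6, 7.13e-6],
        }
    )
    return PaperFixtures(
        table1=table1,
        table2=table2,
        eq16_coeffs=LoadPolynomial(c3=8.9e-21, c2=1.6e-13, c1=-8.3e-7, c0=3.0),
        battery={
            "Q_initial_mAh_g": 63.2,
            "Q_final_mAh_g": 36.35,
            "Csp_initial_F_g": 173.65,
            "Csp_final_F_g": 101.33,
            "fade_pct": 42.48,
            "V_nominal_V": 0.214,
            "ED_Wh_kg": 13.53,
            "Q_theoretical_mAh_g": 89.35,
            "dt_s": 90.0,
            "I_A": 1.0,
            "m_g": 0.5,
            "dV_V": 0.214,
            "n_cycles": 10000,
        },
        averages={"D_mean_cm2_s": 1.95e-7, "mu_mean_cm2_Vs": 7.73e-6},
    )
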
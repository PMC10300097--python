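"""Galvanostatic charge/discharge parsing and battery figure-of-merit
arithmetic.

A GCD profile is a constant-current cycle train: each cycle has one charge
segment (positive current) and one discharge segment (negative current).
From the discharge segment of each cycle the specific capacity
Q = I*dt/m (converted to mAh/g; 1 mAh = 3.6 C) and specific capacitance
Csp = I*dt/(m*dV) (F/g) are computed. Cell-level summaries add the
theoretical capacity zF/M, the gravimetric energy density V*Q
(mAh/g x V = Wh/kg) and the capacity fade/retention split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .constants import CODATA, PhysicalConstants
from .errors import DomainError, InputFormatError

__all__ = [
    "GCDProfile",
    "BatteryInputs",
    "CycleMetrics",
    "BatterySummary",
    "read_gcd_profile",
    "cycle_metrics",
    "theoretical_capacity",
    "energy_density",
    "capacity_fade",
    "battery_summary",
]

#: Coulombs per milliamp-hour.
C_PER_MAH = 3.6


@dataclass(frozen=True)
class GCDProfile:
    """Sampled cycle train: time (s, non-decreasing), voltage (V), signed
    current (A, discharge negative) and a per-sample cycle index."""

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    cycle_index: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        voltage = np.asarray(self.voltage, dtype=float)
        current = np.asarray(self.current, dtype=float)
        cycles = np.asarray(self.cycle_index, dtype=int)
        for name, arr in (("voltage", voltage), ("current", current), ("cycle_index", cycles)):
            if arr.shape != time.shape:
                raise InputFormatError(f"{name} length differs from time")
        if time.size == 0:
            raise InputFormatError("empty profile")
        if np.any(np.diff(time) < 0):
            raise InputFormatError("time must be non-decreasing")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "voltage", voltage)
        object.__setattr__(self, "current", current)
        object.__setattr__(self, "cycle_index", cycles)

    @property
    def n_cycles(self) -> int:
        return int(np.unique(self.cycle_index).size)


class BatteryInputs(BaseModel):
    """Cell bookkeeping: electroactive mass, discharge current, charge number,
    molar mass of the active material and the nominal cell voltage."""

    model_config = ConfigDict(frozen=True)

    m: float = Field(default=0.5, gt=0, description="electroactive mass, g")
    I: float = Field(default=1.0, gt=0, description="discharge current magnitude, A")
    z: int = Field(default=1, ge=1, description="charge number")
    M: float = Field(default=300.0, gt=0, description="molar mass, g/mol")
    V_nominal: float = Field(default=0.214, gt=0, description="nominal voltage, V")


@dataclass(frozen=True)
class CycleMetrics:
    """Discharge metrics of one cycle."""

    cycle: int
    dt_discharge: float  #: s
    dV: float  #: V
    Q: float  #: specific capacity, mAh/g
    Csp: float  #: specific capacitance, F/g (NaN when dV == 0)


@dataclass(frozen=True)
class BatterySummary:
    Q_initial: float  #: mAh/g
    Q_final: float  #: mAh/g
    fade_pct: float
    retention_pct: float
    ED: float  #: Wh/kg
    Q_theoretical: float  #: mAh/g


def _infer_cycles(current: np.ndarray) -> np.ndarray:
    """Cycle labels from current sign: a new cycle starts where the current
    turns positive after a negative (discharge) run."""
    sign = np.sign(current)
    starts = np.zeros(current.size, dtype=int)
    starts[1:] = (sign[1:] > 0) & (sign[:-1] < 0)
    return np.cumsum(starts) + 1


def read_gcd_profile(path: str | Path) -> GCDProfile:
    """Read a CSV cycle train with header ``time_s,voltage_V,current_A[,cycle]``.

    When the optional ``cycle`` column is absent, cycles are inferred from
    sign changes of the current.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    required = {"time_s", "voltage_V", "current_A"}
    missing = required - set(frame.columns)
    if missing:
        raise InputFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if frame.empty:
        raise InputFormatError(f"{path}: no samples")
    time = frame["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) < 0):
        raise InputFormatError(f"{path}: time column is not sorted")
    current = frame["current_A"].to_numpy(dtype=float)
    if "cycle" in frame.columns:
        cycles = frame["cycle"].to_numpy(dtype=int)
    else:
        cycles = _infer_cycles(current)
    return GCDProfile(time, frame["voltage_V"].to_numpy(dtype=float), current, cycles)


def cycle_metrics(profile: GCDProfile, inputs: BatteryInputs) -> pd.DataFrame:
    """Per-cycle discharge metrics.

    The discharge segment of a cycle is its maximal run of negative current;
    dt is the time between the run's endpoints and dV the magnitude of the
    voltage span across it. Cycles without a discharge segment are skipped;
    a zero voltage span yields a missing capacitance with a warning.
    """
    rows = []
    for cycle in np.unique(profile.cycle_index):
        mask = profile.cycle_index == cycle
        current = profile.current[mask]
        time = profile.time[mask]
        voltage = profile.voltage[mask]
        neg = current < 0
        if not neg.any():
            continue
        # Maximal (longest) run of negative current.
        idx = np.flatnonzero(neg)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        run = max(splits, key=len)
        dt = float(time[run[-1]] - time[run[0]])
        dv = float(abs(voltage[run[0]] - voltage[run[-1]]))
        q = inputs.I * dt / inputs.m / C_PER_MAH
        if dv == 0.0:
            warnings.warn(
                f"cycle {int(cycle)}: zero discharge voltage span, capacitance undefined",
                stacklevel=2,
            )
            csp = float("nan")
        else:
            csp = inputs.I * dt / (inputs.m * dv)
        rows.append(
            CycleMetrics(cycle=int(cycle), dt_discharge=dt, dV=dv, Q=q, Csp=csp).__dict__
        )
    if not rows:
        raise DomainError("profile contains no discharge segment")
    return pd.DataFrame(rows)


def theoretical_capacity(
    z: int, M: float, consts: PhysicalConstants = CODATA
) -> float:
    """z F / M expressed in mAh/g (F in C/mol; divide by 3.6 C/mAh)."""
    if not (M > 0):
        raise DomainError(f"molar mass must be positive, got {M}")
    return z * consts.F / M / C_PER_MAH


def energy_density(V_nominal: float, Q: float) -> float:
    """Gravimetric energy density V*Q in Wh/kg (mAh/g x V = Wh/kg)."""
    if not (V_nominal > 0 and Q > 0):
        raise DomainError("V_nominal and Q must be positive")
    return V_nominal * Q


def capacity_fade(Q_initial: float, Q_final: float) -> tuple[float, float]:
    """(fade %, retention %) between the first and last cycle capacities."""
    if not (Q_initial > 0):
        raise DomainError(f"Q_initial must be positive, got {Q_initial}")
    retention = 100.0 * Q_final / Q_initial
    return 100.0 - retention, retention


def battery_summary(
    metrics: pd.DataFrame,
    inputs: BatteryInputs,
    consts: PhysicalConstants = CODATA,
) -> BatterySummary:
    """Cell summary from a per-cycle metrics table (first vs last cycle)."""
    ordered = metrics.sort_values("cycle")
    q_i = float(ordered["Q"].iloc[0])
    q_f = float(ordered["Q"].iloc[-1])
    fade, retention = capacity_fade(q_i, q_f)
    return BatterySummary(
        Q_initial=q_i,
        Q_final=q_f,
        fade_pct=fade,
        retention_pct=retention,
        ED=energy_density(inputs.V_nominal, q_i),
        Q_theoretical=theoretical_capacity(inputs.z, inputs.M, consts),
    )
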
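"""Cyclic-voltammetry peak extraction and the Butler-Volmer energetics chain.

A voltammogram is a potential sweep (V vs Ag/AgCl) with the cell current
recorded at a fixed scan rate. The chain implemented here goes

    i_p  ->  i_0 = i_p/A  ->  dG = |RT ln(i_0 A h / (n F k_B T C))| (eV)
         ->  R_ct = RT/(n F i_0)  ->  rho = R_ct A / l  ->  sigma = 1/rho
         ->  k_het = (k_B T/h) exp(-dG e/(k_B T))

where the concentration ``C`` enters as its numeric value in mol/L and the
charge-transfer resistance is reported as the bare tabulated number obtained
with ``i_0`` in A/m^2 (see docs/methods.md for the unit bookkeeping these
conventions imply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CODATA, ElectrodeConfig, KineticsParams, PhysicalConstants
from .errors import ConfigurationError, DomainError, GeometryError, InputFormatError

__all__ = [
    "CVTrace",
    "Peak",
    "PeakSet",
    "EnergeticsRow",
    "read_cv_trace",
    "write_cv_trace",
    "detect_peaks",
    "free_energy_adsorption",
    "charge_transfer_resistance",
    "resistivity_conductivity",
    "heterogeneous_rate",
    "exchange_current_density",
    "build_energetics_table",
    "DEFAULT_PEAK_WINDOWS",
]

#: Default potential windows (V) for the three features seen on the traces:
#: tubulin adsorption on the forward sweep near +0.3 V, desorption on the
#: reverse sweep near -0.3 V and hydrogen evolution near +0.05 V.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "adsorption": (0.2, 0.4),
    "desorption": (-0.4, -0.2),
    "her": (0.0, 0.1),
}

#: Sweep direction each named feature is expected on (+1 forward / -1 reverse).
_PEAK_DIRECTIONS = {"adsorption": +1, "desorption": -1, "her": -1}

#: Minimum baseline-corrected amplitude (A) for a feature to be reported.
DEFAULT_PROMINENCE = 0.1e-6


@dataclass(frozen=True)
class CVTrace:
    """One voltammogram: swept potential, current and its monotone segments.

    ``segments`` is a list of ``(start, stop)`` index ranges (half-open) over
    which the potential is strictly monotone; they are recomputed from sign
    changes of the potential increments when not supplied.
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        potential = np.asarray(self.potential, dtype=float)
        current = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "potential", potential)
        object.__setattr__(self, "current", current)
        if potential.ndim != 1 or potential.shape != current.shape:
            raise InputFormatError("potential and current must be 1-D and equal length")
        if potential.size < 2:
            raise InputFormatError("a trace needs at least 2 samples")
        if not (self.scan_rate > 0):
            raise DomainError(f"scan_rate must be positive, got {self.scan_rate}")
        if not self.segments:
            object.__setattr__(self, "segments", _find_segments(potential))

    def segment_direction(self, seg: tuple[int, int]) -> int:
        """+1 for a forward (anodic, increasing-potential) segment, -1 reverse."""
        start, stop = seg
        return 1 if self.potential[stop - 1] > self.potential[start] else -1


def _find_segments(potential: np.ndarray) -> list[tuple[int, int]]:
    dv = np.diff(potential)
    if np.any(dv == 0):
        raise InputFormatError("potential sweep contains repeated consecutive values")
    signs = np.sign(dv)
    boundaries = np.flatnonzero(signs[1:] != signs[:-1]) + 1
    edges = [0, *(int(b) for b in boundaries), len(potential) - 1]
    return [(edges[i], edges[i + 1] + 1) for i in range(len(edges) - 1)]


@dataclass(frozen=True)
class Peak:
    """A baseline-corrected voltammetric feature."""

    potential: float  #: E_p, V
    current: float  #: signed baseline-corrected extremum current, A

    @property
    def magnitude(self) -> float:
        """|i_p|, A."""
        return abs(self.current)


@dataclass(frozen=True)
class PeakSet:
    """Named peaks found on a trace; a missing feature is simply absent."""

    peaks: dict[str, Peak] = field(default_factory=dict)

    def __contains__(self, label: str) -> bool:
        return label in self.peaks

    def __getitem__(self, label: str) -> Peak:
        return self.peaks[label]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class EnergeticsRow:
    """One scan-rate row of the derived energetics table."""

    scan_rate: float  #: V/s
    load: float  #: MOhm
    i_p: float  #: peak current magnitude, A
    i_0: float  #: exchange current density, A/m^2
    dG: float  #: adsorption free-energy magnitude, eV
    R_ct: float  #: charge-transfer resistance (tabulated numeric value)
    rho: float  #: resistivity, tabulated Ohm*m
    sigma: float  #: conductivity, S/m
    k_het: float  #: heterogeneous rate constant, 1/s

    def __post_init__(self) -> None:
        if not (self.i_p > 0 and self.R_ct > 0):
            raise DomainError("EnergeticsRow requires i_p > 0 and R_ct > 0")
        if not math.isclose(self.sigma * self.rho, 1.0, rel_tol=1e-9):
            raise DomainError("sigma must be the reciprocal of rho")


def read_cv_trace(path: str | Path, scan_rate: float) -> CVTrace:
    """Read a two-column CSV voltammogram (header ``potential_V,current_A``).

    Raises :class:`InputFormatError` naming the offending line for malformed
    rows, non-numeric cells or fewer than two samples.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    missing = {"potential_V", "current_A"} - set(frame.columns)
    if missing:
        raise InputFormatError(
            f"{path}: line 1: missing required column(s) {sorted(missing)}"
        )
    values = {}
    for col in ("potential_V", "current_A"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering.
            raise InputFormatError(
                f"{path}: line {int(bad[0]) + 2}: non-numeric value "
                f"{frame[col].iloc[int(bad[0])]!r} in column {col}"
            )
        values[col] = numeric.to_numpy(dtype=float)
    if len(frame) < 2:
        raise InputFormatError(f"{path}: fewer than 2 samples")
    return CVTrace(values["potential_V"], values["current_A"], scan_rate)


def write_cv_trace(trace: CVTrace, path: str | Path) -> Path:
    """Write a trace in the same CSV dialect ``read_cv_trace`` accepts.

    Values are written with 17 significant digits so a write/read round trip
    reproduces the float64 samples exactly.
    """
    path = Path(path)
    frame = pd.DataFrame({"potential_V": trace.potential, "current_A": trace.current})
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def detect_peaks(
    trace: CVTrace,
    windows: Mapping[str, tuple[float, float]] | None = None,
    prominence: float = DEFAULT_PROMINENCE,
) -> PeakSet:
    """Locate baseline-corrected peaks inside labelled potential windows.

    For each window a straight baseline through the first and last in-window
    samples of the candidate sweep segment is subtracted; the extremum of the
    corrected current gives (E_p, i_p). Features whose corrected amplitude
    falls below ``prominence`` are omitted. Windows named after the known
    features ("adsorption", "desorption", "her") are searched only on the
    sweep direction that feature belongs to; other labels search every
    segment.
    """
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS
    lo_all, hi_all = trace.potential.min(), trace.potential.max()
    found: dict[str, Peak] = {}
    for label, (lo, hi) in windows.items():
        if lo >= hi:
            raise GeometryError(f"window {label!r}: empty interval ({lo}, {hi})")
        if hi < lo_all or lo > hi_all:
            raise GeometryError(
                f"window {label!r} ({lo}, {hi}) lies outside the trace potential "
                f"range ({lo_all}, {hi_all})"
            )
        direction = _PEAK_DIRECTIONS.get(label)
        best: Peak | None = None
        n_samples = 0
        for seg in trace.segments:
            if direction is not None and trace.segment_direction(seg) != direction:
                continue
            start, stop = seg
            e = trace.potential[start:stop]
            i = trace.current[start:stop]
            mask = (e >= lo) & (e <= hi)
            n_samples += int(mask.sum())
            if mask.sum() < 3:
                continue
            e_w, i_w = e[mask], i[mask]
            # Linear baseline through the window edges.
            slope = (i_w[-1] - i_w[0]) / (e_w[-1] - e_w[0])
            corrected = i_w - (i_w[0] + slope * (e_w - e_w[0]))
            k = int(np.argmax(np.abs(corrected)))
            if abs(corrected[k]) < prominence:
                continue
            if best is None or abs(corrected[k]) > abs(best.current):
                best = Peak(float(e_w[k]), float(corrected[k]))
        if n_samples == 0:
            raise GeometryError(f"window {label!r} ({lo}, {hi}) contains no samples")
        if best is not None:
            found[label] = best
    return PeakSet(found)


def free_energy_adsorption(
    i_p: float,
    cfg: ElectrodeConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> float:
    """Adsorption free-energy magnitude |RT ln(i_p h/(n F k_B T C))| in eV.

    ``i_p`` is the peak-current magnitude in A; the area cancels because
    i_0*A = i_p. The concentration enters as its numeric value in mol/L.
    """
    cfg = cfg or ElectrodeConfig()
    if not (i_p > 0):
        raise DomainError(f"i_p must be positive, got {i_p}")
    argument = i_p * consts.h / (cfg.n * consts.F * consts.k_B * cfg.T * cfg.C_MT)
    dg_joule_per_mol = consts.R * cfg.T * math.log(argument)
    return abs(dg_joule_per_mol) / consts.F  # J/mol -> eV since R = F k_B/e


def charge_transfer_resistance(
    i_p: float,
    cfg: ElectrodeConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> float:
    """Charge-transfer resistance RT/(n F i_0) with i_0 = i_p/A.

    Returned as the bare tabulated number (i_0 in A/m^2 with A in m^2;
    dimensionally Ohm*m^2 — reproduced as printed, not repaired).
    """
    cfg = cfg or ElectrodeConfig()
    if not (i_p > 0):
        raise DomainError(f"i_p must be positive, got {i_p}")
    i_0 = i_p / cfg.A
    return consts.R * cfg.T / (cfg.n * consts.F * i_0)


def resistivity_conductivity(
    r_ct: float, cfg: ElectrodeConfig | None = None
) -> tuple[float, float]:
    """(rho, sigma) = (R_ct*A/l, 1/rho)."""
    cfg = cfg or ElectrodeConfig()
    if not (r_ct > 0):
        raise DomainError(f"R_ct must be positive, got {r_ct}")
    rho = r_ct * cfg.A / cfg.l
    return rho, 1.0 / rho


def heterogeneous_rate(
    dG: float, T: float = 298.15, consts: PhysicalConstants = CODATA
) -> float:
    """Arrhenius/Eyring rate (k_B T/h) exp(-dG e/(k_B T)), dG in eV."""
    if not (T > 0):
        raise DomainError(f"T must be positive, got {T}")
    return consts.k_B * T / consts.h * math.exp(-dG * consts.e / (consts.k_B * T))


def exchange_current_density(
    cfg: ElectrodeConfig,
    kin: KineticsParams,
    k_het: float,
    consts: PhysicalConstants = CODATA,
) -> float:
    """Butler-Volmer exchange current density, symbol placement taken literally:

        i_0 = (n F C_MT k_het / A) * exp(beta n F E_step / (k_B T))

    The exponent mixes molar (F) and molecular (k_B) scales exactly as the
    source expression does; no downstream tabulated number constrains it, so
    the formula is reproduced verbatim (see docs/methods.md).
    """
    prefactor = cfg.n * consts.F * cfg.C_MT * k_het / cfg.A
    exponent = kin.beta * cfg.n * consts.F * kin.E_step / (consts.k_B * cfg.T)
    return prefactor * math.exp(exponent)


def build_energetics_table(
    peaks: Mapping[float, float],
    loads: Mapping[float, float],
    cfg: ElectrodeConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> pd.DataFrame:
    """Full derived-energetics table, one row per scan rate (ascending).

    Parameters
    ----------
    peaks : mapping scan rate (V/s) -> peak current (A; sign ignored).
    loads : mapping scan rate (V/s) -> applied load (MOhm). Must have the
        same key set as ``peaks``.
    """
    cfg = cfg or ElectrodeConfig()
    if set(peaks) != set(loads):
        raise ConfigurationError(
            f"scan-rate keys differ between peaks {sorted(peaks)} "
            f"and loads {sorted(loads)}"
        )
    rows = []
    for rate in sorted(peaks):
        i_p = abs(peaks[rate])
        dg = free_energy_adsorption(i_p, cfg, consts)
        r_ct = charge_transfer_resistance(i_p, cfg, consts)
        rho, sigma = resistivity_conductivity(r_ct, cfg)
        rows.append(
            EnergeticsRow(
                scan_rate=rate,
                load=loads[rate],
                i_p=i_p,
                i_0=i_p / cfg.A,
                dG=dg,
                R_ct=r_ct,
                rho=rho,
                sigma=sigma,
                k_het=heterogeneous_rate(dg, cfg.T, consts),
            )
        )
    return pd.DataFrame([row.__dict__ for row in rows])


def peaks_from_traces(
    traces: Mapping[float, CVTrace],
    windows: Mapping[str, tuple[float, float]] | None = None,
    label: str = "adsorption",
    prominence: float = DEFAULT_PROMINENCE,
) -> dict[float, float]:
    """Convenience: extract one labelled peak magnitude per trace."""
    out: dict[float, float] = {}
    for rate, trace in traces.items():
        peak_set = detect_peaks(trace, windows, prominence)
        if label not in peak_set:
            raise GeometryError(f"no {label!r} peak found at scan rate {rate}")
        out[rate] = peak_set[label].magnitude
    return out
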
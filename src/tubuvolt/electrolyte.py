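"""Ionic-conductance model of the KCl electrolyte with a microtubule
saturation rule.

The electrolyte conductance follows the molar-conductance relation
G = Lambda0 * C * A / l (C converted from mol/L to mol/cm^3 internally).
The microtubule count enters through an explicitly phenomenological
saturation rule: once the number of tubulin units in the box reaches a
critical threshold the conductance drops by a fixed factor and then stays
constant — the step-then-plateau behaviour seen when self-assembly saturates
the available counterions. The threshold and drop factor are knobs, not
measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError

__all__ = ["IonicModelConfig", "ConductanceGrid", "ionic_conductance", "conductance_sweep"]


class IonicModelConfig(BaseModel):
    """Electrolyte geometry, composition and the saturation knobs."""

    model_config = ConfigDict(frozen=True)

    lambda0: float = Field(default=73.5, gt=0, description="molar conductance of K+, S cm^2/mol")
    C_KCl: float = Field(default=0.4, ge=0, description="KCl concentration, mol/L")
    A_cell: float = Field(default=1.0, gt=0, description="electrode cross-section, cm^2")
    l_cell: float = Field(default=1.0, gt=0, description="electrode separation, cm")
    n_MT: int = Field(default=1, ge=0, description="microtubule unit count")
    critical_n: int = Field(default=1500, ge=1, description="saturation threshold, units")
    drop_factor: float = Field(default=0.5, gt=0, le=1, description="conductance drop at threshold")


@dataclass(frozen=True)
class ConductanceGrid:
    """Long-format table over (C_KCl, n_MT) with the conductance G in S."""

    table: pd.DataFrame

    def pivot(self) -> pd.DataFrame:
        """n_MT rows x C_KCl columns view of the grid."""
        return self.table.pivot(index="n_MT", columns="C_KCl", values="G_S")


def ionic_conductance(cfg: IonicModelConfig) -> float:
    """G = Lambda0 * C * A / l in siemens, with C converted to mol/cm^3."""
    return cfg.lambda0 * (cfg.C_KCl / 1000.0) * cfg.A_cell / cfg.l_cell


def conductance_sweep(
    base: IonicModelConfig,
    kcl_grid: Sequence[float],
    n_mt_grid: Sequence[int],
) -> ConductanceGrid:
    """Evaluate the conductance over a (KCl concentration, MT count) grid.

    Below ``critical_n`` the tubulin units leave the electrolyte conductance
    unchanged; at and above it the conductance is multiplied by
    ``drop_factor`` and held constant in the MT count.
    """
    if not len(kcl_grid) or not len(n_mt_grid):
        raise ConfigurationError("kcl_grid and n_mt_grid must be nonempty")
    records = []
    for c in kcl_grid:
        g0 = ionic_conductance(base.model_copy(update={"C_KCl": float(c)}))
        for n in n_mt_grid:
            factor = base.drop_factor if n >= base.critical_n else 1.0
            records.append({"C_KCl": float(c), "n_MT": int(n), "G_S": g0 * factor})
    return ConductanceGrid(table=pd.DataFrame(records))
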
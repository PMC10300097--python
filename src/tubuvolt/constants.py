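"""Physical constants and shared experiment geometry.

All electrochemical estimators in this package are driven by a small set of
physical constants (CODATA 2018 exact values by default) and an electrode
description: exposed area ``A``, an effective conduction path length ``l``
used to turn charge-transfer resistance into a resistivity, the number of
electrons transferred ``n``, temperature ``T`` and the tubulin concentration
``C_MT`` entered as its numeric value in mol/L (the convention that
reproduces the tabulated free energies; see docs/methods.md).
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator


class PhysicalConstants(BaseModel):
    """Fundamental constants used across the estimator chain.

    Attributes
    ----------
    F : Faraday constant, C/mol.
    R : molar gas constant, J/(mol K).
    k_B : Boltzmann constant, J/K.
    h : Planck constant, J s.
    e : elementary charge, C — used for J <-> eV conversion.
    """

    model_config = ConfigDict(frozen=True)

    F: float = Field(default=96485.33212331001, gt=0)
    R: float = Field(default=8.31446261815324, gt=0)
    k_B: float = Field(default=1.380649e-23, gt=0)
    h: float = Field(default=6.62607015e-34, gt=0)
    e: float = Field(default=1.602176634e-19, gt=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "PhysicalConstants":
        # R = F k_B / e (i.e. R = N_A k_B) must hold to 1e-6 relative;
        # it is what makes (RT/F)·ln(...) equal (k_B T/e)·ln(...) in eV.
        implied_R = self.F * self.k_B / self.e
        if not math.isclose(implied_R, self.R, rel_tol=1e-6):
            raise ValueError(
                f"inconsistent constants: F*k_B/e = {implied_R!r} but R = {self.R!r}"
            )
        return self


class ElectrodeConfig(BaseModel):
    """Working-electrode geometry and cell conditions.

    ``A`` is the area exposed to the electrolyte (m^2), ``l`` the effective
    conduction path length (m) used in rho = R_ct*A/l, ``n`` the electrons
    transferred per event, ``T`` the temperature (K) and ``C_MT`` the tubulin
    concentration whose *numeric value in mol/L* enters the free-energy
    logarithm.
    """

    model_config = ConfigDict(frozen=True)

    A: float = Field(default=5.0e-4, gt=0, description="electrode area, m^2")
    l: float = Field(default=1.0e-6, gt=0, description="conduction path length, m")
    n: int = Field(default=1, ge=1, description="electrons transferred")
    T: float = Field(default=298.15, gt=0, description="temperature, K")
    C_MT: float = Field(default=1.0e-3, gt=0, description="tubulin concentration, mol/L")


class KineticsParams(BaseModel):
    """Butler-Volmer kinetics inputs: symmetry factor and step potential."""

    model_config = ConfigDict(frozen=True)

    beta: float = Field(default=0.5, gt=0, lt=1, description="symmetry factor")
    E_step: float = Field(default=0.0, description="step potential, V")


#: Module-level default constants, shared by operations that take none explicitly.
CODATA = PhysicalConstants()
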
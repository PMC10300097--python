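"""Stochastic box model of tubulin transfer from bulk to the electrode wall.

Two coarse-grained walkers — one alpha-tubulin, one beta-tubulin — start at
the centre of a cubic box whose walls stand for the gold electrode surface,
``d_total`` angstroms away. Each proposal advances a walker by a fixed
displacement ``delta_d = x * (t/t_eq)`` (solvation radius times the
load-controlled time fraction); a Boltzmann gate on the chemical-potential
gap between the two tubulin species decides whether the move is taken. The
walk ends when the first walker comes within the Au-S bond distance ``d1``
of the wall, and the dimerization energy is the difference of the two
species' configuration energies at that moment:

    E_i(species) = E_species + d2/d1 + (d + ephiapp)/d_total       (eV-equivalents)
    E_ad         = E_i1 - E_i2

The distance-over-distance and distance-plus-potential terms are numeric
bookkeeping in eV-equivalents, reproduced exactly as specified by the model;
no dimensional repair is attempted (docs/methods.md discusses this and the
acceptance-gate conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CODATA, PhysicalConstants
from .errors import ConfigurationError, ConvergenceError, DomainError, StateError
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MCConfig",
    "WalkerState",
    "MCTrajectory",
    "MCSweepResult",
    "LoadPolynomial",
    "step_displacement",
    "misc_energy",
    "config_energies",
    "chemical_potentials",
    "acceptance_threshold",
    "acceptance_gate",
    "run_walk",
    "dimerization_energy",
    "load_sweep",
    "fit_load_response",
    "evaluate_load_polynomial",
    "PAPER_LOADS_MOHM",
]

#: The six applied loads (MOhm) paired with the CV scan rates.
PAPER_LOADS_MOHM: tuple[float, ...] = (1.81, 2.21, 3.85, 5.13, 7.35, 8.00)

AcceptanceConvention = Literal["paper_ge", "metropolis_le"]


class MCConfig(BaseModel):
    """Box-model parameters.

    ``acceptance_convention`` selects how the uniform draw is compared with
    the Boltzmann threshold: ``paper_ge`` accepts when draw >= threshold (the
    source model's printed criterion) and ``metropolis_le`` accepts when
    draw <= min(1, threshold) (the standard Metropolis rule). The printed
    direction gives zero acceptance when the two chemical potentials are
    equal, hence the explicit flag.
    """

    model_config = ConfigDict(frozen=True)

    d_total: float = Field(default=690.0, gt=0, description="box half-length, A")
    d1: float = Field(default=2.39, gt=0, description="Au-S bond distance, A")
    x: float = Field(default=3.0, gt=0, description="tubulin solvation radius, A")
    E_amt: float = Field(default=0.286, description="alpha-tubulin/Au energy, eV")
    E_bmt: float = Field(default=0.293, description="beta-tubulin/Au energy, eV")
    ephiapp: float = Field(default=1.0, description="applied potential, V")
    t_over_teq: float = Field(default=1.0, ge=0, description="time fraction per step")
    n_units: int = Field(default=1500, ge=1, description="tubulin unit count")
    n_seeds: int = Field(default=1000, ge=1, description="replicate count")
    T: float = Field(default=298.15, gt=0, description="temperature, K")
    rng_seed: int = Field(default=0, description="master RNG seed")
    acceptance_convention: AcceptanceConvention = "paper_ge"
    symmetric_paths: bool = Field(
        default=False,
        description="share one draw per step so both walkers move in lockstep",
    )
    step_cap: int = Field(default=2_000_000, gt=0, description="proposal limit")

    @model_validator(mode="after")
    def _check_geometry(self) -> "MCConfig":
        if not (self.d_total > self.d1):
            raise ValueError("d_total must exceed the critical distance d1")
        if not (1 <= self.n_units <= 1500):
            # Overridable in principle, but the model was exercised over 1..1500.
            raise ValueError("n_units must lie in 1..1500")
        return self


@dataclass(frozen=True)
class WalkerState:
    """Snapshot of one walker."""

    species: Literal["alpha", "beta"]
    d: float  #: distance travelled from the box centre, A
    remaining: float  #: distance left to the wall, A
    E_i: float  #: configuration energy, eV
    mu: float  #: chemical potential, eV
    step_count: int


@dataclass(frozen=True)
class MCTrajectory:
    """Per-proposal history of one paired walk.

    Arrays all have length ``steps_to_contact`` (number of proposals until
    the first walker reached the wall). Positions are post-move; draws and
    accepted flags are recorded per walker (the symmetric mode shares one
    draw, duplicated into both columns).
    """

    d_alpha: np.ndarray
    d_beta: np.ndarray
    e_mis_alpha: np.ndarray
    e_mis_beta: np.ndarray
    e_i1: np.ndarray
    e_i2: np.ndarray
    draws_alpha: np.ndarray
    draws_beta: np.ndarray
    accepted_alpha: np.ndarray
    accepted_beta: np.ndarray
    d2: float
    delta_d: float
    threshold: float
    terminated: bool
    steps_to_contact: int

    @property
    def acceptance_rate(self) -> float:
        """Fraction of accepted proposals pooled over both walkers."""
        flags = np.concatenate([self.accepted_alpha, self.accepted_beta])
        return float(flags.mean()) if flags.size else float("nan")


@dataclass(frozen=True)
class LoadPolynomial:
    """Cubic E_ad(L) = c3 L^3 + c2 L^2 + c1 L + c0, L in MOhm, E_ad in eV."""

    c3: float
    c2: float
    c1: float
    c0: float
    load_units: str = "MOhm"


@dataclass(frozen=True)
class MCSweepResult:
    """Per-load summary of replicate walks.

    ``table`` has columns ``load_Mohm, mean_Ead_eV, sd_eV, acceptance_rate,
    n_seeds`` where ``mean_Ead_eV`` is the mean of |E_ad| over replicates and
    ``sd_eV`` its spread across replicates (NaN when n_seeds < 2).
    """

    table: pd.DataFrame


def step_displacement(cfg: MCConfig) -> tuple[float, float]:
    """(delta_d, d2): per-step displacement and the per-step covered distance."""
    delta_d = cfg.x * cfg.t_over_teq
    return delta_d, cfg.d1 + delta_d


def misc_energy(d: float, ephiapp: float, d_total: float) -> float:
    """Solvation/miscellaneous term (d + ephiapp)/d_total, taken literally.

    ``d`` in angstroms and ``ephiapp`` in volts are mixed numerically; the
    result is treated as an eV-equivalent bookkeeping term.
    """
    if np.any(np.asarray(d) < 0) or np.any(np.asarray(d) > d_total):
        raise DomainError(f"d must lie in [0, d_total], got {d}")
    return (d + ephiapp) / d_total


def config_energies(
    state_pair: tuple[WalkerState, WalkerState], cfg: MCConfig
) -> tuple[float, float]:
    """(E_i1, E_i2) for an (alpha, beta) walker pair, each at its own position."""
    alpha, beta = state_pair
    _, d2 = step_displacement(cfg)
    e_i1 = cfg.E_amt + d2 / cfg.d1 + misc_energy(alpha.d, cfg.ephiapp, cfg.d_total)
    e_i2 = cfg.E_bmt + d2 / cfg.d1 + misc_energy(beta.d, cfg.ephiapp, cfg.d_total)
    return e_i1, e_i2


def chemical_potentials(e_i1: float, e_i2: float, ephiapp: float) -> tuple[float, float]:
    """(mu1, mu2) = (E_i1 - ephiapp, E_i2 - ephiapp)."""
    return e_i1 - ephiapp, e_i2 - ephiapp


def acceptance_threshold(
    mu1: float, mu2: float, T: float, consts: PhysicalConstants = CODATA
) -> float:
    """Boltzmann threshold exp(-F (mu2 - mu1)/(R T)), the gap in volt-equivalents."""
    if not (T > 0):
        raise DomainError(f"T must be positive, got {T}")
    return math.exp(-consts.F * (mu2 - mu1) / (consts.R * T))


def acceptance_gate(
    mu1: float,
    mu2: float,
    T: float,
    draw,
    convention: AcceptanceConvention = "paper_ge",
    consts: PhysicalConstants = CODATA,
):
    """Accept/reject a proposal given a uniform(0,1) draw (scalar or array).

    ``paper_ge`` accepts when draw >= threshold (the model's printed
    criterion); ``metropolis_le`` accepts when draw <= min(1, threshold).
    """
    threshold = acceptance_threshold(mu1, mu2, T, consts)
    draw = np.asarray(draw)
    if convention == "paper_ge":
        accepted = draw >= threshold
    elif convention == "metropolis_le":
        accepted = draw <= min(1.0, threshold)
    else:  # pragma: no cover - guarded by typing
        raise ConfigurationError(f"unknown acceptance convention {convention!r}")
    return bool(accepted) if accepted.ndim == 0 else accepted


def _accept_mask(draws: np.ndarray, threshold: float, convention: str) -> np.ndarray:
    if convention == "paper_ge":
        return draws >= threshold
    return draws <= min(1.0, threshold)


def run_walk(cfg: MCConfig, seed: int, consts: PhysicalConstants = CODATA) -> MCTrajectory:
    """Simulate one paired alpha/beta walk; identical (cfg, seed) -> identical output.

    Each walker's gate evaluates the two species' chemical potentials at that
    walker's own position, so the gap reduces to the constant species gap
    E_bmt - E_amt and the Boltzmann threshold is the same for every proposal
    (evaluating the gate on the separated pair makes the printed ``>=``
    criterion absorbing; see docs/methods.md). The walk terminates when the
    first walker's remaining distance drops below d1.
    """
    rng = np.random.default_rng(seed)
    delta_d, d2 = step_displacement(cfg)
    travel = cfg.d_total - cfg.d1  # contact once d > travel
    mu_gap = cfg.E_bmt - cfg.E_amt  # mu2 - mu1 at co-located evaluation
    threshold = math.exp(-consts.F * mu_gap / (consts.R * cfg.T))
    if cfg.acceptance_convention == "paper_ge":
        p_accept = max(0.0, 1.0 - threshold)
    else:
        p_accept = min(1.0, threshold)

    if delta_d <= 0 or p_accept <= 0:
        # No proposal can ever advance a walker: report a convergence failure
        # at the configured cap rather than looping forever.
        raise ConvergenceError(
            f"walk cannot reach the wall (delta_d={delta_d}, acceptance "
            f"probability {p_accept}); step cap {cfg.step_cap} would be exceeded"
        )

    k_contact = math.floor(travel / delta_d) + 1  # accepted steps to contact
    draws_a = np.empty(0)
    draws_b = np.empty(0)
    # Draw in growing blocks until one walker has enough accepted steps.
    block = max(256, int(1.5 * k_contact / p_accept))
    while True:
        if cfg.symmetric_paths:
            new = rng.random(block)
            draws_a = np.concatenate([draws_a, new])
            draws_b = draws_a
        else:
            new = rng.random((2, block))
            draws_a = np.concatenate([draws_a, new[0]])
            draws_b = np.concatenate([draws_b, new[1]])
        acc_a = _accept_mask(draws_a, threshold, cfg.acceptance_convention)
        acc_b = _accept_mask(draws_b, threshold, cfg.acceptance_convention)
        counts_a = np.cumsum(acc_a)
        counts_b = np.cumsum(acc_b)
        hit_a = np.flatnonzero(counts_a == k_contact)
        hit_b = np.flatnonzero(counts_b == k_contact)
        if hit_a.size or hit_b.size:
            break
        if draws_a.size >= cfg.step_cap:
            raise ConvergenceError(
                f"no wall contact within step cap {cfg.step_cap} "
                f"(delta_d={delta_d}, p_accept={p_accept:.4g})"
            )
        block = min(block * 2, cfg.step_cap)

    first_a = int(hit_a[0]) if hit_a.size else np.iinfo(np.int64).max
    first_b = int(hit_b[0]) if hit_b.size else np.iinfo(np.int64).max
    n_steps = min(first_a, first_b) + 1

    acc_a = acc_a[:n_steps]
    acc_b = acc_b[:n_steps]
    d_alpha = delta_d * counts_a[:n_steps]
    d_beta = delta_d * counts_b[:n_steps]
    e_mis_a = (d_alpha + cfg.ephiapp) / cfg.d_total
    e_mis_b = (d_beta + cfg.ephiapp) / cfg.d_total
    geom = d2 / cfg.d1
    return MCTrajectory(
        d_alpha=d_alpha,
        d_beta=d_beta,
        e_mis_alpha=e_mis_a,
        e_mis_beta=e_mis_b,
        e_i1=cfg.E_amt + geom + e_mis_a,
        e_i2=cfg.E_bmt + geom + e_mis_b,
        draws_alpha=draws_a[:n_steps],
        draws_beta=draws_b[:n_steps],
        accepted_alpha=acc_a,
        accepted_beta=acc_b,
        d2=d2,
        delta_d=delta_d,
        threshold=threshold,
        terminated=True,
        steps_to_contact=n_steps,
    )


def dimerization_energy(
    traj: MCTrajectory, reduction: Literal["terminal", "mean"] = "terminal"
) -> float:
    """E_ad = E_i1 - E_i2 at the terminal step (default) or averaged over steps."""
    if not traj.terminated:
        raise StateError("trajectory has not reached the wall")
    diff = traj.e_i1 - traj.e_i2
    if reduction == "terminal":
        return float(diff[-1])
    if reduction == "mean":
        return float(diff.mean())
    raise ConfigurationError(f"unknown reduction {reduction!r}")


def default_load_mapping(loads: Sequence[float]) -> dict[float, float]:
    """t/t_eq proportional to load, normalised to 1 at the maximum load."""
    top = max(loads)
    return {load: load / top for load in loads}


def load_sweep(
    cfg: MCConfig,
    loads: Sequence[float] = PAPER_LOADS_MOHM,
    load_to_tfrac: Mapping[float, float] | None = None,
    n_seeds: int | None = None,
    reduction: Literal["terminal", "mean"] = "terminal",
    consts: PhysicalConstants = CODATA,
) -> MCSweepResult:
    """Replicate walks at each load; summarise mean/sd of |E_ad|.

    Replicate ``r`` at every load uses seed ``cfg.rng_seed + r``, so the
    whole sweep is reproducible from the master seed. ``sd_eV`` is NaN when
    fewer than two replicates are requested.
    """
    if not loads:
        raise ConfigurationError("loads must be nonempty")
    mapping = dict(load_to_tfrac) if load_to_tfrac is not None else default_load_mapping(loads)
    missing = [load for load in loads if load not in mapping]
    if missing:
        raise ConfigurationError(f"load_to_tfrac lacks entries for loads {missing}")
    n = n_seeds if n_seeds is not None else cfg.n_seeds
    rows = []
    for load in loads:
        run_cfg = cfg.model_copy(update={"t_over_teq": mapping[load]})
        e_ad = np.empty(n)
        acc = np.empty(n)
        for r in range(n):
            traj = run_walk(run_cfg, cfg.rng_seed + r, consts)
            e_ad[r] = dimerization_energy(traj, reduction)
            acc[r] = traj.acceptance_rate
        magnitudes = np.abs(e_ad)
        rows.append(
            {
                "load_Mohm": load,
                "mean_Ead_eV": float(magnitudes.mean()),
                "sd_eV": float(magnitudes.std(ddof=1)) if n >= 2 else float("nan"),
                "acceptance_rate": float(acc.mean()),
                "n_seeds": n,
            }
        )
    return MCSweepResult(table=pd.DataFrame(rows))


def fit_load_response(sweep: MCSweepResult) -> LoadPolynomial:
    """Least-squares cubic of mean E_ad on load (MOhm)."""
    table = sweep.table
    loads = table["load_Mohm"].to_numpy(dtype=float)
    if np.unique(loads).size < 4:
        raise ConfigurationError(
            f"need >= 4 distinct loads for a cubic fit, got {np.unique(loads).size}"
        )
    means = table["mean_Ead_eV"].to_numpy(dtype=float)
    series = np.polynomial.Polynomial.fit(loads, means, deg=3).convert()
    c0, c1, c2, c3 = (float(c) for c in series.coef)
    return LoadPolynomial(c3=c3, c2=c2, c1=c1, c0=c0)


def evaluate_load_polynomial(p: LoadPolynomial, load: float) -> float:
    """E_ad(L) = c3 L^3 + c2 L^2 + c1 L + c0."""
    return ((p.c3 * load + p.c2) * load + p.c1) * load + p.c0
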
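"""Box-model walk mechanics, acceptance gate and the load response."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tubuvolt as tv
from tubuvolt.errors import ConfigurationError, ConvergenceError, DomainError
from tubuvolt.mc_engine import PAPER_LOADS_MOHM, WalkerState, default_load_mapping


# --------------------------------------------------------- step arithmetic


@pytest.mark.parametrize(
    "t_frac, expected_dd, expected_d2",
    [(0.0, 0.0, 2.39), (1.0, 3.0, 5.39), (0.5, 1.5, 3.89)],
)
def test_step_displacement(t_frac, expected_dd, expected_d2):
    cfg = tv.MCConfig(t_over_teq=t_frac)
    dd, d2 = tv.step_displacement(cfg)
    assert dd == pytest.approx(expected_dd, abs=1e-15)
    assert d2 == pytest.approx(expected_d2, abs=1e-15)


@pytest.mark.parametrize(
    "d, ephiapp, expected",
    [(345.0, 0.0, 0.5), (0.0, 0.0, 0.0), (345.0, 0.5, 345.5 / 690.0)],
)
def test_misc_energy(d, ephiapp, expected):
    assert tv.misc_energy(d, ephiapp, 690.0) == pytest.approx(expected, rel=1e-12)


def test_misc_energy_domain():
    with pytest.raises(DomainError):
        tv.misc_energy(-1.0, 0.0, 690.0)


def test_config_energies_at_start():
    cfg = tv.MCConfig(t_over_teq=0.0, ephiapp=0.0)
    alpha = WalkerState("alpha", 0.0, 690.0, 0.0, 0.0, 0)
    beta = WalkerState("beta", 0.0, 690.0, 0.0, 0.0, 0)
    e1, e2 = tv.config_energies((alpha, beta), cfg)
    assert e1 == pytest.approx(1.286, abs=1e-12)
    assert e2 == pytest.approx(1.293, abs=1e-12)
    assert e1 - e2 == pytest.approx(cfg.E_amt - cfg.E_bmt, abs=1e-12)


def test_chemical_potentials():
    mu1, mu2 = tv.chemical_potentials(1.286, 1.293, 0.3)
    assert mu1 == pytest.approx(0.986, abs=1e-12)
    assert (mu2 - mu1) == pytest.approx(1.293 - 1.286, abs=1e-12)


# -------------------------------------------------------- acceptance gate


def test_acceptance_threshold_closed_form(consts):
    thr = tv.acceptance_threshold(0.0, 0.007, 298.15, consts)
    assert thr == pytest.approx(
        math.exp(-consts.F * 0.007 / (consts.R * 298.15)), rel=1e-12
    )
    assert thr == pytest.approx(0.7615, abs=5e-5)


def test_acceptance_gate_conventions():
    assert tv.acceptance_gate(0.0, 0.007, 298.15, 0.80, "paper_ge") is True
    assert tv.acceptance_gate(0.0, 0.007, 298.15, 0.70, "paper_ge") is False
    assert tv.acceptance_gate(0.0, 0.007, 298.15, 0.70, "metropolis_le") is True
    # equal chemical potentials: the printed direction never accepts
    assert tv.acceptance_gate(0.5, 0.5, 298.15, 0.999, "paper_ge") is False
    assert tv.acceptance_gate(0.5, 0.5, 298.15, 0.999, "metropolis_le") is True


@pytest.mark.parametrize("convention", ["paper_ge", "metropolis_le"])
def test_gate_empirical_frequency_matches_analytic(convention, consts):
    n = 100_000
    rng = np.random.default_rng(2024)
    draws = rng.random(n)
    accepted = tv.acceptance_gate(0.0, 0.007, 298.15, draws, convention)
    thr = tv.acceptance_threshold(0.0, 0.007, 298.15, consts)
    p = 1.0 - thr if convention == "paper_ge" else min(1.0, thr)
    sd = math.sqrt(p * (1 - p) / n)
    assert abs(accepted.mean() - p) <= 3 * sd


# ---------------------------------------------------------------- the walk


def test_forced_acceptance_walk_is_deterministic_arithmetic():
    # equal species energies + Metropolis direction => threshold 1, always accept
    cfg = tv.MCConfig(E_bmt=0.286, acceptance_convention="metropolis_le", t_over_teq=1.0)
    traj = tv.run_walk(cfg, seed=5)
    assert traj.steps_to_contact == math.ceil((690.0 - 2.39) / 3.0)  # 230
    assert traj.acceptance_rate == 1.0


def test_same_seed_gives_identical_trajectories(mc_config):
    a = tv.run_walk(mc_config, seed=99)
    b = tv.run_walk(mc_config, seed=99)
    np.testing.assert_array_equal(a.d_alpha, b.d_alpha)
    np.testing.assert_array_equal(a.draws_beta, b.draws_beta)
    assert tv.dimerization_energy(a) == tv.dimerization_energy(b)


def test_walk_acceptance_rate_matches_gate_frequency(mc_config, consts):
    traj = tv.run_walk(mc_config, seed=7)
    p = 1.0 - traj.threshold
    n = traj.steps_to_contact * 2
    sd = math.sqrt(p * (1 - p) / n)
    assert abs(traj.acceptance_rate - p) <= 3 * sd


def test_zero_displacement_is_a_convergence_failure():
    cfg = tv.MCConfig(t_over_teq=0.0, step_cap=1000)
    with pytest.raises(ConvergenceError):
        tv.run_walk(cfg, seed=1)


def test_trajectory_replay_reproduces_dimerization_energy(mc_config):
    """Hand-replaying the recorded bookkeeping gives the reported E_ad."""
    traj = tv.run_walk(mc_config, seed=3)
    cfg = mc_config
    geom = traj.d2 / cfg.d1
    e1 = cfg.E_amt + geom + (traj.d_alpha[-1] + cfg.ephiapp) / cfg.d_total
    e2 = cfg.E_bmt + geom + (traj.d_beta[-1] + cfg.ephiapp) / cfg.d_total
    assert tv.dimerization_energy(traj, "terminal") == pytest.approx(e1 - e2, abs=1e-15)
    diffs = traj.e_i1 - traj.e_i2
    assert tv.dimerization_energy(traj, "mean") == pytest.approx(diffs.mean(), abs=1e-15)
    # positions advance only on accepted proposals, by exactly delta_d
    steps = np.diff(np.concatenate([[0.0], traj.d_alpha]))
    np.testing.assert_allclose(
        steps, traj.accepted_alpha * traj.delta_d, rtol=0, atol=1e-12
    )


def test_symmetric_paths_pin_dimerization_energy(mc_config):
    cfg = mc_config.model_copy(update={"symmetric_paths": True})
    traj = tv.run_walk(cfg, seed=21)
    np.testing.assert_array_equal(traj.d_alpha, traj.d_beta)
    assert tv.dimerization_energy(traj) == pytest.approx(cfg.E_amt - cfg.E_bmt, abs=1e-15)


# ------------------------------------------------------------- load sweep


def test_sweep_sd_of_mean_shrinks_with_replicates(mc_config):
    small = tv.load_sweep(mc_config, loads=[8.0], n_seeds=100)
    large = tv.load_sweep(mc_config, loads=[8.0], n_seeds=400)
    sem_small = small.table["sd_eV"].iloc[0] / math.sqrt(100)
    sem_large = large.table["sd_eV"].iloc[0] / math.sqrt(400)
    assert sem_small / sem_large == pytest.approx(2.0, rel=0.35)


def test_sweep_monotone_within_one_sd(mc_config):
    sweep = tv.load_sweep(mc_config, loads=list(PAPER_LOADS_MOHM), n_seeds=200)
    t = sweep.table
    means, sds = t["mean_Ead_eV"].to_numpy(), t["sd_eV"].to_numpy()
    assert np.all(means[1:] <= means[:-1] + sds[:-1])
    assert ((t["acceptance_rate"] > 0.2) & (t["acceptance_rate"] < 0.3)).all()


def test_degenerate_mapping_makes_loads_exchangeable(mc_config):
    mapping = {load: 0.5 for load in PAPER_LOADS_MOHM}
    sweep = tv.load_sweep(
        mc_config, loads=list(PAPER_LOADS_MOHM), load_to_tfrac=mapping, n_seeds=150
    )
    t = sweep.table
    sems = t["sd_eV"] / math.sqrt(150)
    spread = t["mean_Ead_eV"].max() - t["mean_Ead_eV"].min()
    assert spread <= 4 * sems.max()


def test_sweep_single_seed_reports_missing_sd(mc_config):
    sweep = tv.load_sweep(mc_config, loads=[8.0], n_seeds=1)
    assert math.isnan(sweep.table["sd_eV"].iloc[0])
    with pytest.raises(ConfigurationError):
        tv.load_sweep(mc_config, loads=[8.0], load_to_tfrac={4.0: 1.0})


def test_default_mapping_normalises_at_maximum_load():
    mapping = default_load_mapping(PAPER_LOADS_MOHM)
    assert mapping[8.00] == 1.0
    assert mapping[1.81] == pytest.approx(1.81 / 8.00)


# ------------------------------------------------------------- cubic fit


def test_cubic_fit_recovers_exact_coefficients():
    truth = tv.LoadPolynomial(c3=0.002, c2=-0.05, c1=0.3, c0=2.5)
    loads = np.linspace(1.0, 9.0, 12)
    import pandas as pd

    table = pd.DataFrame(
        {
            "load_Mohm": loads,
            "mean_Ead_eV": [tv.evaluate_load_polynomial(truth, x) for x in loads],
            "sd_eV": 0.0,
            "acceptance_rate": 0.5,
            "n_seeds": 1,
        }
    )
    fit = tv.fit_load_response(tv.MCSweepResult(table=table))
    for name in ("c3", "c2", "c1", "c0"):
        assert getattr(fit, name) == pytest.approx(getattr(truth, name), abs=1e-9)


def test_cubic_fit_of_constant_data_is_constant():
    import pandas as pd

    table = pd.DataFrame(
        {
            "load_Mohm": [1.0, 2.0, 3.0, 4.0, 5.0],
            "mean_Ead_eV": [1.5] * 5,
            "sd_eV": 0.0,
            "acceptance_rate": 0.5,
            "n_seeds": 1,
        }
    )
    fit = tv.fit_load_response(tv.MCSweepResult(table=table))
    assert fit.c0 == pytest.approx(1.5, abs=1e-9)
    for name in ("c1", "c2", "c3"):
        assert getattr(fit, name) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ConfigurationError):
        tv.fit_load_response(tv.MCSweepResult(table=table.iloc[:3]))


def test_noisy_regression_recovers_intercept():
    rng = np.random.default_rng(8)
    truth = tv.LoadPolynomial(c3=0.0, c2=0.0, c1=-0.2, c0=3.0)
    loads = np.tile(np.linspace(1, 9, 10), 100)
    values = np.array(
        [tv.evaluate_load_polynomial(truth, x) for x in loads]
    ) + rng.normal(0, 0.05, loads.size)
    import pandas as pd

    table = pd.DataFrame(
        {
            "load_Mohm": loads,
            "mean_Ead_eV": values,
            "sd_eV": 0.05,
            "acceptance_rate": 0.5,
            "n_seeds": 1,
        }
    )
    fit = tv.fit_load_response(tv.MCSweepResult(table=table))
    assert fit.c0 == pytest.approx(3.0, abs=0.05)  # ~3 se for this design


def test_published_load_polynomial_limits(fixtures):
    poly = fixtures.eq16_coeffs
    assert tv.evaluate_load_polynomial(poly, 0.0) == 3.0
    assert tv.evaluate_load_polynomial(poly, 1.0) == pytest.approx(
        3.0 - 8.3e-7 + 1.6e-13 + 8.9e-21, rel=1e-15
    )


@given(st.floats(min_value=-5, max_value=5), st.floats(min_value=-5, max_value=5))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_polynomial_at_zero_is_the_constant_term(c0, c1):
    poly = tv.LoadPolynomial(c3=1.0, c2=-2.0, c1=c1, c0=c0)
    assert tv.evaluate_load_polynomial(poly, 0.0) == c0
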
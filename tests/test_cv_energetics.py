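"""Voltammogram IO, peak detection and the Butler-Volmer energetics chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tubuvolt as tv
from tubuvolt.config import DEFAULT_LOADS_BY_SCAN_RATE
from tubuvolt.errors import (
    ConfigurationError,
    DomainError,
    GeometryError,
    InputFormatError,
)
from tubuvolt.synthetic import CVSynthParams, SynthPeak, synth_cv_trace


# ---------------------------------------------------------------- trace IO


def test_single_monotone_sweep_is_one_segment():
    trace = tv.CVTrace([-1.0, -0.5, 0.5, 1.0], [0.0, 1e-6, 2e-6, 3e-6], scan_rate=0.05)
    assert trace.segments == [(0, 4)]
    assert trace.segment_direction((0, 4)) == 1


def test_triangular_sweep_splits_at_apex():
    potential = [-1.0, 0.0, 1.0, 0.0, -1.0]
    trace = tv.CVTrace(potential, [0.0] * 5, scan_rate=0.05)
    assert trace.segments == [(0, 3), (2, 5)]
    assert trace.segment_direction(trace.segments[1]) == -1


def test_write_read_round_trip_is_exact(tmp_path):
    params = CVSynthParams(
        scan_rate=0.05,
        peaks=(SynthPeak(center=0.3, width=0.02, amplitude=1e-5),),
        noise_sd=2e-7,
        seed=7,
    )
    trace = synth_cv_trace(params)
    path = tv.write_cv_trace(trace, tmp_path / "trace.csv")
    back = tv.read_cv_trace(path, scan_rate=0.05)
    np.testing.assert_allclose(back.potential, trace.potential, rtol=0, atol=1e-12)
    np.testing.assert_allclose(back.current, trace.current, rtol=0, atol=1e-18)
    assert back.segments == trace.segments


@pytest.mark.parametrize(
    "content, fragment",
    [
        ("potential_V,current_A\n0.1,abc\n0.2,1e-6\n", "line 2"),
        ("potential_V,current_A\n0.1,1e-6\n", "fewer than 2"),
        ("volts,current_A\n0.1,1e-6\n0.2,2e-6\n", "potential_V"),
    ],
)
def test_malformed_trace_files_are_reported_with_location(tmp_path, content, fragment):
    path = tmp_path / "bad.csv"
    path.write_text(content)
    with pytest.raises(InputFormatError, match=fragment):
        tv.read_cv_trace(path, scan_rate=0.05)


# ---------------------------------------------------------- peak detection


def test_flat_trace_yields_no_peaks():
    params = CVSynthParams(scan_rate=0.05, capacitive_baseline=0.0)
    peaks = tv.detect_peaks(synth_cv_trace(params))
    assert len(peaks) == 0


def test_injected_anodic_peak_recovered_within_tolerance():
    params = CVSynthParams(
        scan_rate=0.05,
        peaks=(SynthPeak(center=0.30, width=0.02, amplitude=10e-6),),
        noise_sd=0.05e-6,
        seed=11,
    )
    peaks = tv.detect_peaks(synth_cv_trace(params))
    assert "adsorption" in peaks
    peak = peaks["adsorption"]
    assert peak.magnitude == pytest.approx(10e-6, rel=0.02)
    assert abs(peak.potential - 0.30) <= 0.010


def test_fixture_traces_recover_tabulated_peak_currents(fixtures):
    traces = tv.table1_fixture_traces()
    peaks = tv.peaks_from_traces(traces)
    for _, row in fixtures.table1.iterrows():
        assert peaks[row["scan_rate_Vps"]] == pytest.approx(abs(row["ip_A"]), rel=0.01)


def test_empty_window_raises_geometry_error():
    params = CVSynthParams(scan_rate=0.05)
    trace = synth_cv_trace(params)
    with pytest.raises(GeometryError):
        tv.detect_peaks(trace, {"stray": (5.0, 6.0)})


# ------------------------------------------------------- energetics chain


def test_free_energy_matches_tabulated_endpoints(fixtures, electrode, consts):
    table = fixtures.table1
    low = tv.free_energy_adsorption(abs(table["ip_A"].iloc[0]), electrode, consts)
    high = tv.free_energy_adsorption(abs(table["ip_A"].iloc[-1]), electrode, consts)
    assert round(low, 2) == table["dG_eV"].iloc[0]
    assert round(high, 2) == table["dG_eV"].iloc[-1]


def test_free_energy_zero_at_unit_log_argument(electrode, consts):
    i_p = electrode.n * consts.F * consts.k_B * electrode.T * electrode.C_MT / consts.h
    assert tv.free_energy_adsorption(i_p, electrode, consts) == pytest.approx(0.0, abs=1e-12)


def test_free_energy_invariant_under_electrode_area(consts):
    small = tv.ElectrodeConfig(A=5.0e-4)
    large = tv.ElectrodeConfig(A=5.0e-3)
    for i_p in (5.52e-6, 25.0e-6):
        assert tv.free_energy_adsorption(i_p, small, consts) == pytest.approx(
            tv.free_energy_adsorption(i_p, large, consts), rel=1e-12
        )
    with pytest.raises(DomainError):
        tv.free_energy_adsorption(-1e-6, small, consts)


def test_charge_transfer_resistance_values_and_scaling(fixtures, electrode, consts):
    assert round(tv.charge_transfer_resistance(5.52e-6, electrode, consts), 2) == 2.33
    assert round(tv.charge_transfer_resistance(13.0e-6, electrode, consts), 2) == 0.99
    r = tv.charge_transfer_resistance(7e-6, electrode, consts)
    assert tv.charge_transfer_resistance(14e-6, electrode, consts) == pytest.approx(
        r / 2, rel=1e-12
    )


def test_rct_times_ip_constant_across_rows(fixtures, electrode, consts):
    products = [
        tv.charge_transfer_resistance(abs(ip), electrode, consts) * abs(ip)
        for ip in fixtures.table1["ip_A"]
    ]
    expected = consts.R * electrode.T * electrode.A / (electrode.n * consts.F)
    np.testing.assert_allclose(products, expected, rtol=1e-9)


def test_resistivity_conductivity_reproduce_highest_load_row(electrode, consts):
    r_ct = tv.charge_transfer_resistance(25.0e-6, electrode, consts)
    rho, sigma = tv.resistivity_conductivity(r_ct, electrode)
    assert round(sigma * 1e3, 2) == 3.89  # mS/m
    assert rho == pytest.approx(256.78, rel=1e-3)


@given(st.floats(min_value=1e-9, max_value=1e-2))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_sigma_is_reciprocal_of_rho(i_p):
    cfg = tv.ElectrodeConfig()
    rho, sigma = tv.resistivity_conductivity(
        tv.charge_transfer_resistance(i_p, cfg), cfg
    )
    assert sigma * rho == pytest.approx(1.0, rel=1e-12)


def test_heterogeneous_rate_prefactor_and_closed_form(consts):
    assert tv.heterogeneous_rate(0.0, 298.15, consts) == pytest.approx(
        consts.k_B * 298.15 / consts.h, rel=1e-12
    )
    # independent high-precision evaluation of the closed form
    import sympy

    dg = 1.19
    kb = sympy.Float(consts.k_B, 30)
    h = sympy.Float(consts.h, 30)
    e = sympy.Float(consts.e, 30)
    T = sympy.Float(298.15, 30)
    oracle = float(kb * T / h * sympy.exp(-sympy.Float(dg, 30) * e / (kb * T)))
    assert tv.heterogeneous_rate(dg, 298.15, consts) == pytest.approx(oracle, rel=1e-12)
    assert tv.heterogeneous_rate(1.2, 298.15, consts) < tv.heterogeneous_rate(
        1.1, 298.15, consts
    )


def test_exchange_current_density_limits(electrode, consts):
    k_het = 1.0e3
    base = tv.exchange_current_density(
        electrode, tv.KineticsParams(beta=0.5, E_step=0.0), k_het, consts
    )
    assert base == pytest.approx(
        electrode.n * consts.F * electrode.C_MT * k_het / electrode.A, rel=1e-12
    )
    # doubling E_step multiplies by the same exponential factor again
    e_step = 1e-25  # keeps the literal molar/molecular exponent representable
    once = tv.exchange_current_density(
        electrode, tv.KineticsParams(beta=0.5, E_step=e_step), k_het, consts
    )
    twice = tv.exchange_current_density(
        electrode, tv.KineticsParams(beta=0.5, E_step=2 * e_step), k_het, consts
    )
    assert twice / once == pytest.approx(once / base, rel=1e-9)


# ------------------------------------------------------------ full table


def test_energetics_table_reproduces_published_columns(fixtures, electrode, consts):
    table1 = fixtures.table1
    peaks = dict(zip(table1["scan_rate_Vps"], table1["ip_A"].abs()))
    loads = dict(zip(table1["scan_rate_Vps"], table1["load_Mohm"]))
    out = tv.build_energetics_table(peaks, loads, electrode, consts)
    assert list(out["scan_rate"]) == sorted(peaks)
    np.testing.assert_array_equal(out["dG"].round(2), table1["dG_eV"])
    np.testing.assert_array_equal(out["R_ct"].round(2), table1["R_ct"])
    # conductivity strictly increases with peak current at fixed geometry
    assert out["sigma"].is_monotonic_increasing


def test_energetics_table_rows_are_independent(electrode, consts):
    full = tv.build_energetics_table(
        {0.01: 5.52e-6, 0.2: 25.0e-6}, {0.01: 1.81, 0.2: 8.00}, electrode, consts
    )
    single = tv.build_energetics_table({0.01: 5.52e-6}, {0.01: 1.81}, electrode, consts)
    assert single.shape[0] == 1
    assert single.iloc[0]["dG"] == full.iloc[0]["dG"]
    with pytest.raises(ConfigurationError):
        tv.build_energetics_table({0.01: 5.52e-6}, {0.02: 1.81}, electrode, consts)


def test_default_load_pairing_matches_published_table(fixtures):
    assert DEFAULT_LOADS_BY_SCAN_RATE == dict(
        zip(fixtures.table1["scan_rate_Vps"], fixtures.table1["load_Mohm"])
    )


def test_inconsistent_physical_constants_rejected():
    with pytest.raises(Exception, match="inconsistent"):
        tv.PhysicalConstants(F=96500.0)
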
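import math

import numpy as np
import pytest

from ipsccm import Model, Parameters
from ipsccm import _core
from ipsccm.currents import (RTF, compute_currents, gating_rhs, ncx_current,
                             ion_concentration_rhs, reversal_potentials)


@pytest.fixture(scope="module")
def model():
    return Model()


@pytest.fixture(scope="module")
def rest_state(model):
    return model.initial_state()


def _with_gates_open(model, y, v):
    y = y.copy()
    y[_core.IV] = v
    y[1:14] = 1.0  # all HH gates fully open
    return y


def test_potassium_currents_null_at_ek(model, rest_state):
    ek = reversal_potentials(model, rest_state)["e_k"]
    y = _with_gates_open(model, rest_state, ek)
    cur = compute_currents(model, y)
    assert cur["i_k1"] == pytest.approx(0.0, abs=1e-12)
    assert cur["i_kr"] == pytest.approx(0.0, abs=1e-12)
    assert cur["i_to"] == pytest.approx(0.0, abs=1e-12)


def test_sodium_current_null_at_ena(model, rest_state):
    ena = reversal_potentials(model, rest_state)["e_na"]
    y = _with_gates_open(model, rest_state, ena)
    assert compute_currents(model, y)["i_na"] == pytest.approx(0.0, abs=1e-12)


def test_ncx_null_at_equilibrium_potential(model, rest_state):
    sv = model.view(rest_state)
    e_na = RTF * math.log(model.params.nao / sv.nai)
    e_ca = 0.5 * RTF * math.log(model.params.cao / sv.ca_sl)
    v_eq = 3 * e_na - 2 * e_ca
    assert ncx_current(v_eq, sv.nai, sv.ca_sl, model) == pytest.approx(0.0, abs=1e-12)


def test_ncx_moves_toward_reverse_mode_with_depolarization(model, rest_state):
    sv = model.view(rest_state)
    vs = np.linspace(-80.0, -60.0, 21)
    cur = [ncx_current(v, sv.nai, sv.ca_sl, model) for v in vs]
    assert np.all(np.diff(cur) > 0)  # monotonically less forward (inward)


def test_ncx_linear_in_scale_factor(model, rest_state):
    sv = model.view(rest_state)
    a = ncx_current(-70.0, sv.nai, sv.ca_sl, model, k_ncx=1000.0)
    b = ncx_current(-70.0, sv.nai, sv.ca_sl, model, k_ncx=2000.0)
    assert b == pytest.approx(2 * a, rel=1e-12)


def test_full_ncx_block_zeroes_current_everywhere(model, rest_state):
    for v in (-80.0, -40.0, 0.0, 40.0):
        y = _with_gates_open(model, rest_state, v)
        cur = compute_currents(model, y, block_factors={"NCX": 1.0})
        assert cur["i_ncx"] == 0.0


def test_block_factor_range_validated(model, rest_state):
    with pytest.raises(ValueError):
        compute_currents(model, rest_state, block_factors={"NCX": 1.2})


def test_nonfinite_state_is_an_integration_fault(model, rest_state):
    bad = rest_state.copy()
    bad[0] = np.nan
    with pytest.raises(FloatingPointError):
        compute_currents(model, bad)


def test_gate_at_steady_state_has_zero_rate(model, rest_state):
    xinf, xtau = model.gating_rates(rest_state)
    y = rest_state.copy()
    mask = xtau > 0
    y[mask] = xinf[mask]
    rates = gating_rhs(model, y)
    assert np.allclose(rates[mask], 0.0, atol=1e-12)


def test_gate_rates_finite_over_physiological_range(model, rest_state):
    for v in np.linspace(-120.0, 80.0, 41):
        y = rest_state.copy()
        y[_core.IV] = v
        rates = gating_rhs(model, y)
        assert np.all(np.isfinite(rates))


def test_voltage_clamped_gate_relaxes_exponentially(model, rest_state):
    """Under clamp, a gate started at 0 follows 1 - exp(-t/tau) toward its
    steady state (closed-form solution of the linear gate ODE)."""
    from ipsccm.simulate import run_segments

    y = rest_state.copy()
    v_hold = -20.0
    y[_core.IV] = v_hold
    xinf, xtau = model.gating_rates(y)
    gate = _core.IXS  # slow gate: tau >> dt so the discretization is clean
    y[gate] = 0.0
    t_end = xtau[gate]  # integrate exactly one time constant
    tr = run_segments(model, [(0.0, t_end, {_core.D_CLAMP: 1.0})], y)
    expected = xinf[gate] * (1 - math.exp(-1.0))
    assert tr.meta["final_state"][gate] == pytest.approx(expected, rel=2e-2)


def test_gates_remain_in_unit_interval(paced_trace):
    gates = paced_trace.y[:, 1:14]
    assert gates.min() >= -1e-12
    assert gates.max() <= 1.0 + 1e-12


def test_charge_bookkeeping_identity(model, rest_state):
    """Sum of z-weighted ion fluxes equals the total membrane current."""
    for v in (-75.0, -40.0, 0.0, 20.0):
        y = _with_gates_open(model, rest_state, v)
        cur = model.currents(y)
        conc = ion_concentration_rhs(model, y)
        kconv = model.params.cm * 1000.0 / (_core.FARADAY * model.vol_cyto)
        lhs = -(conc["d_nai"] + conc["d_ki"] + 2.0 * conc["j_ca_mem"]) / kconv
        assert lhs == pytest.approx(cur["i_tot"], rel=1e-9, abs=1e-9)


def test_all_currents_zero_gives_zero_ion_rates(model, rest_state):
    m = model
    for tgt in ("I_Na", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1", "I_f",
                "NCX", "NKA", "PMCA", "backgrounds"):
        m = m.scale(tgt, 0.0)
    y = rest_state.copy()
    conc = ion_concentration_rhs(m, y)
    assert conc["d_nai"] == pytest.approx(0.0, abs=1e-15)
    assert conc["d_ki"] == pytest.approx(0.0, abs=1e-15)


def test_ical_step_protocol_peaks_near_zero_mv(model, rest_state):
    """Brute-force evaluation of activation x driving force across the step
    protocol: the peak L-type current falls in the 0..+10 mV steps."""
    steps = np.arange(-30.0, 50.1, 10.0)
    peaks = []
    for v in steps:
        d_inf = 1.0 / (1.0 + math.exp(-(v + 9.1) / 6.0))
        peaks.append(d_inf * (v - 60.0))
    best = steps[int(np.argmin(peaks))]
    assert best in (0.0, 10.0)
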
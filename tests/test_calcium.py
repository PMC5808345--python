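import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from ipsccm import Parameters, build_grid
from ipsccm.calcium import (buffering_rhs, diffusion_matrix, diffusion_rhs,
                            serca_flux, sr_release_flux)

PARAMS = Parameters()
GRID = build_grid(10.0, 20)


# ---------------------------------------------------------------- diffusion
def test_uniform_field_has_zero_diffusion():
    ca = np.full(GRID.n_shells, 2.3e-4)
    assert np.allclose(diffusion_rhs(ca, GRID, PARAMS), 0.0, atol=1e-18)


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        diffusion_rhs(np.ones(5), GRID, PARAMS)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(1e-6, 1e-2), min_size=20, max_size=20))
def test_diffusion_conserves_mass(vals):
    ca = np.array(vals)
    dca = diffusion_rhs(ca, GRID, PARAMS)
    va = PARAMS.vol_cyto_frac * GRID.volumes
    assert abs(np.dot(dca, va)) <= 1e-12 * np.dot(np.abs(ca), va)


def test_two_compartment_exchange_matches_closed_form():
    """A concentration step between two coupled compartments decays
    exponentially at the analytic rate g*(1/V1 + 1/V2)."""
    grid = build_grid(10.0, 20)
    va = PARAMS.vol_cyto_frac * grid.volumes
    g = PARAMS.d_ca * grid.areas[-2] / grid.dr  # outermost interface
    v1, v2 = va[-2], va[-1]
    L2 = np.array([[-g / v1, g / v1], [g / v2, -g / v2]])
    lam_expected = -g * (1 / v1 + 1 / v2)
    ca0 = np.array([1e-4, 3e-4])
    sol = solve_ivp(lambda t, c: L2 @ c, (0, 2.0), ca0, rtol=1e-11, atol=1e-15,
                    t_eval=[0.0, 1.0])
    diff0 = ca0[1] - ca0[0]
    diff1 = sol.y[1, 1] - sol.y[0, 1]
    measured = np.log(diff1 / diff0) / 1.0
    assert measured == pytest.approx(lam_expected, rel=1e-6)
    # and the full operator has one conserved mode, all others decaying
    L = diffusion_matrix(grid, PARAMS)
    eig = np.sort(np.real(np.linalg.eigvals(L)))
    assert abs(eig[-1]) < 1e-10
    assert np.all(eig[:-1] < 0)


# ---------------------------------------------------------------- release
def test_release_zero_when_closed_or_equilibrated():
    assert sr_release_flux(1e-4, 0.5, PARAMS, open_prob_override=0.0) == 0.0
    assert sr_release_flux(0.5, 0.5, PARAMS, open_prob_override=0.7) == 0.0


def test_release_override_validated():
    with pytest.raises(ValueError):
        sr_release_flux(1e-4, 0.5, PARAMS, open_prob_override=1.5)


def test_release_only_system_converges_to_common_concentration():
    """With SERCA and the L-type current off, a half-open RyR drives SR and
    cytosolic Ca monotonically toward a common value."""
    p = PARAMS
    vs, vc = 1.0, 10.0  # SR much smaller than cytosol

    def rhs(t, y):
        ca, casr = y
        j = sr_release_flux(ca, casr, p, open_prob_override=0.5)
        return [j, -j * vc / vs]

    sol = solve_ivp(rhs, (0, 4e5), [1e-4, 0.8], rtol=1e-9, atol=1e-12, max_step=2e3)
    ca, casr = sol.y[:, -1]
    assert ca == pytest.approx(casr, rel=1e-3)
    gaps = sol.y[1] - sol.y[0]
    assert np.all(np.diff(gaps) <= 1e-6)  # monotone (solver noise tolerated)


# ---------------------------------------------------------------- SERCA
def test_serca_forward_term_zero_at_zero_ca():
    assert serca_flux(0.0, 0.5, PARAMS) <= 0.0


def test_serca_monotone_in_cytosolic_ca():
    cas = np.linspace(0.0, 2e-3, 50)
    fluxes = [serca_flux(c, 0.5, PARAMS) for c in cas]
    assert np.all(np.diff(fluxes) > 0)


def test_serca_half_saturation():
    p = PARAMS.replace(serca_kleak=0.0)
    half = serca_flux(p.serca_km, 0.5, p)
    assert half == pytest.approx(p.serca_vmax / 2, rel=1e-12)


def test_serca_rejects_negative_concentrations():
    with pytest.raises(ValueError):
        serca_flux(-1e-4, 0.5, PARAMS)


# ---------------------------------------------------------------- buffering
def test_zero_buffer_gives_zero_correction():
    p = PARAMS.replace(buf1_tot=0.0, buf2_tot=0.0, fluo_tot=0.0)
    ca = np.full(4, 3e-4)
    bound = np.zeros((3, 4))
    d_bound, d_ca = buffering_rhs(ca, bound, p)
    assert np.allclose(d_bound, 0.0)
    assert np.allclose(d_ca, 0.0)


def test_buffer_equilibrium_occupancy_is_stationary():
    p = PARAMS
    ca = np.array([1e-4, 5e-4])
    kd = np.array([p.buf1_koff / p.buf1_kon, p.buf2_koff / p.buf2_kon,
                   p.fluo_koff / p.fluo_kon])
    tot = np.array([p.buf1_tot, p.buf2_tot, p.fluo_tot])
    bound = tot[:, None] * ca[None, :] / (ca[None, :] + kd[:, None])
    d_bound, _ = buffering_rhs(ca, bound, p)
    assert np.allclose(d_bound, 0.0, atol=1e-12)


@settings(max_examples=20, deadline=None)
@given(st.floats(1e-5, 5e-3), st.floats(0.0, 1.0))
def test_buffering_conserves_total_ca(ca_val, frac):
    p = PARAMS.replace(fluo_tot=0.002)
    ca = np.array([ca_val])
    tot = np.array([p.buf1_tot, p.buf2_tot, p.fluo_tot])
    bound = (frac * tot)[:, None]
    d_bound, d_ca = buffering_rhs(ca, bound, p)
    assert d_ca[0] + d_bound.sum() == pytest.approx(0.0, abs=1e-15)


def test_explicit_kinetics_agree_with_rapid_buffer_limit():
    """For on-rates much faster than the transient, integrating the explicit
    kinetics through a slow Ca ramp tracks the equilibrium occupancy within
    2% (the rapid-buffer approximation)."""
    p = PARAMS
    kd1 = p.buf1_koff / p.buf1_kon

    def rhs(t, y):
        ca = 1e-4 + 4e-4 * min(t / 2000.0, 1.0)  # slow ramp over 2 s
        b = y[0]
        return [p.buf1_kon * ca * (p.buf1_tot - b) - p.buf1_koff * b]

    b0 = p.buf1_tot * 1e-4 / (1e-4 + kd1)
    sol = solve_ivp(rhs, (0, 2000.0), [b0], rtol=1e-9, atol=1e-14)
    ca_end = 5e-4
    b_eq = p.buf1_tot * ca_end / (ca_end + kd1)
    assert sol.y[0, -1] == pytest.approx(b_eq, rel=0.02)
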
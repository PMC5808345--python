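"""Functional surface of the intracellular Ca2+ subsystem.

These functions expose the individual flux laws used by the compiled
right-hand side — radial finite-volume diffusion, RyR/IP3R release, SERCA
uptake and explicit buffering — for direct evaluation and testing.  They
operate on plain arrays; the assembled model evaluates the same physics
inside :mod:`ipsccm._core`.
"""

from __future__ import annotations

import numpy as np

from .geometry import ShellGrid
from .parameters import Parameters

__all__ = ["diffusion_rhs", "diffusion_matrix", "sr_release_flux",
           "serca_flux", "buffering_rhs", "ryr_activation", "luminal_gate"]


def diffusion_matrix(grid: ShellGrid, params: Parameters) -> np.ndarray:
    """Linear operator L with d(ca)/dt = L @ ca for pure radial diffusion.

    Finite-volume form on spherical shells; zero-flux at the center and at
    the sarcolemma (membrane exchange is a separate source term).  The
    operator conserves volume-weighted mass to round-off.
    """
    n = grid.n_shells
    va = params.vol_cyto_frac * grid.volumes
    L = np.zeros((n, n))
    for i in range(n - 1):
        g = params.d_ca * grid.areas[i + 1] / grid.dr
        L[i, i] -= g / va[i]
        L[i, i + 1] += g / va[i]
        L[i + 1, i + 1] -= g / va[i + 1]
        L[i + 1, i] += g / va[i + 1]
    return L


def diffusion_rhs(ca: np.ndarray, grid: ShellGrid, params: Parameters) -> np.ndarray:
    """Per-shell concentration rate (mM/ms) from radial diffusion alone."""
    ca = np.asarray(ca, dtype=float)
    if ca.shape != (grid.n_shells,):
        raise ValueError(
            f"field has {ca.shape} entries, grid has {grid.n_shells} shells")
    return diffusion_matrix(grid, params) @ ca


def ryr_activation(ca_local: float, ca_sr: float, params: Parameters) -> float:
    """Steady-state open fraction of the activation gate (sharp logistic).

    The midpoint falls from ``ryr_ka_max`` toward ``ryr_ka_min`` as the SR
    loads (luminal sensitization with midpoint ``ryr_kasr``).
    """
    s_sr = 1.0 / (1.0 + (params.ryr_kasr / ca_sr) ** params.ryr_hsr)
    ka = params.ryr_ka_max - (params.ryr_ka_max - params.ryr_ka_min) * s_sr
    z = np.clip((ca_local - ka) * params.ryr_ha / ka, -35.0, 35.0)
    return float(1.0 / (1.0 + np.exp(-z)))


def luminal_gate(ca_sr: float, params: Parameters) -> float:
    """Release-flux scaling by SR content (empties -> shuts)."""
    return ca_sr**2 / (ca_sr**2 + params.ryr_klum**2)


def sr_release_flux(ca_local, ca_sr, params: Parameters,
                    open_prob_override: float | None = None,
                    armed: float = 1.0, activation: float | None = None,
                    density: float = 1.0) -> float:
    """RyR release flux (mM/ms, local-shell units) for one relay.

    Flux = nu * density * P_open * luminal_gate * (ca_SR - ca_local), with
    P_open = activation x armed unless overridden (override in [0, 1]).
    """
    if open_prob_override is not None:
        if not 0.0 <= open_prob_override <= 1.0:
            raise ValueError("open-probability override must be in [0, 1]")
        po = open_prob_override
    else:
        a = ryr_activation(ca_local, ca_sr, params) if activation is None else activation
        po = a * armed
    return float(params.ryr_nu * density * po * luminal_gate(ca_sr, params)
                 * (ca_sr - ca_local))


def ip3r_flux(ca_local, ca_sr, params: Parameters) -> float:
    """Constitutive IP3R release (perinuclear; fixed IP3, no PLC dynamics)."""
    return float(params.ip3_nu * params.ip3_po * (ca_sr - ca_local))


def serca_flux(ca_local: float, ca_sr: float, params: Parameters) -> float:
    """Net SERCA flux out of the cytosol (mM/ms): Hill uptake minus SR leak.

    Positive values move Ca into the SR.  The forward term is half-maximal
    at ``serca_km``; the reverse/leak term is linear in the SR gradient.
    """
    if ca_local < 0 or ca_sr < 0:
        raise ValueError("concentrations must be non-negative")
    h = params.serca_hill
    fwd = params.serca_vmax * ca_local**h / (ca_local**h + params.serca_km**h)
    leak = params.serca_kleak * (ca_sr - ca_local)
    return float(fwd - leak)


def buffering_rhs(ca: np.ndarray, bound: np.ndarray, params: Parameters):
    """Mass-action buffer kinetics for the three species.

    ``bound`` has shape (3, n): rows are the calmodulin-like species, the
    troponin/SR-site-like species, and Fluo-4.  Returns ``(d_bound, d_ca)``
    with d_ca the free-Ca correction (the sum of binding rates, negated);
    total Ca (free + bound) is conserved by these terms alone.
    """
    ca = np.asarray(ca, float)
    bound = np.asarray(bound, float)
    tot = np.array([params.buf1_tot, params.buf2_tot, params.fluo_tot])
    kon = np.array([params.buf1_kon, params.buf2_kon, params.fluo_kon])
    koff = np.array([params.buf1_koff, params.buf2_koff, params.fluo_koff])
    d_bound = (kon[:, None] * ca[None, :] * (tot[:, None] - bound)
               - koff[:, None] * bound)
    return d_bound, -d_bound.sum(axis=0)
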
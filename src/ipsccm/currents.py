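"""Functional surface of the sarcolemmal current inventory.

Wrappers over the compiled right-hand side exposing the membrane currents,
gating kinetics and ionic bookkeeping for direct evaluation; plus a
closed-form NCX implementation used as an independent check of the
exchanger's thermodynamics (it must vanish exactly at 3E_Na - 2E_Ca).
"""

from __future__ import annotations

import math

import numpy as np

from . import _core
from .model import Model

__all__ = ["compute_currents", "gating_rhs", "ncx_current",
           "ion_concentration_rhs", "reversal_potentials", "RTF"]

RTF = _core.RTF


def reversal_potentials(model: Model, y: np.ndarray) -> dict:
    sv = model.view(y)
    p = model.params
    return {
        "e_na": RTF * math.log(p.nao / sv.nai),
        "e_k": RTF * math.log(p.ko / sv.ki),
        "e_ca": 0.5 * RTF * math.log(p.cao / sv.ca_sl),
        "e_ks": RTF * math.log((p.ko + 0.03 * p.nao) / (sv.ki + 0.03 * sv.nai)),
    }


def compute_currents(model: Model, y: np.ndarray,
                     block_factors: dict | None = None) -> dict:
    """All membrane currents (pA/pF) at state ``y``.

    ``block_factors`` maps scale-target names to fractional blocks in
    [0, 1]; a factor f multiplies the target's maximum rate by (1 - f).
    Raises on a non-finite state (integration fault signal).
    """
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to compute_currents")
    m = model.with_blocks(block_factors) if block_factors else model
    cur = m.currents(np.asarray(y, float))
    return {k: v for k, v in cur.items() if k.startswith("i_")}


def gating_rhs(model: Model, y: np.ndarray) -> np.ndarray:
    """dx/dt = (x_inf(V) - x)/tau for every Hodgkin-Huxley gate.

    Returns an array aligned with the state vector; non-gate entries are 0.
    """
    xinf, xtau = model.gating_rates(np.asarray(y, float))
    out = np.zeros_like(xinf)
    mask = xtau > 0
    out[mask] = (xinf[mask] - y[mask]) / xtau[mask]
    return out


def ncx_current(v: float, nai: float, ca_sl: float, model: Model | None = None,
                k_ncx: float | None = None) -> float:
    """Electrogenic 3Na:1Ca exchange current density (pA/pF).

    Sign convention: forward mode (Ca extrusion, 3 Na in) is an inward
    (negative) current.  The current is exactly zero at the exchanger
    equilibrium potential 3E_Na - 2E_Ca and linear in the scale factor.
    """
    p = (model or Model()).params
    k = p.k_ncx if k_ncx is None else k_ncx
    ef = math.exp(0.35 * v / RTF)
    er = math.exp(-0.65 * v / RTF)
    num = ef * nai**3 * p.cao - er * p.nao**3 * ca_sl
    den = (87.5**3 + p.nao**3) * (1.38 + p.cao) * (1.0 + 0.1 * er)
    return k * num / den


def ion_concentration_rhs(model: Model, y: np.ndarray) -> dict:
    """d[Na]/dt and d[K]/dt (mM/ms) plus the trans-sarcolemmal Ca flux.

    Stoichiometric sums of the carrying currents (NKA 3:2, NCX 3:1) scaled
    by capacitance, the Faraday constant and the accessible cytosolic
    volume; the Ca flux is handed to the calcium subsystem at the outermost
    shell and is reported here in whole-cytosol units.
    """
    dy = model.rhs(np.asarray(y, float))
    cur = model.currents(np.asarray(y, float))
    return {"d_nai": float(dy[_core.INAI]), "d_ki": float(dy[_core.IKI]),
            "j_ca_mem": float(cur["j_ca_mem"])}
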
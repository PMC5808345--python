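"""Assembled whole-cell model: parameters + geometry + state vector helpers."""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np

from . import _core
from ._core import CUR_NAMES, NCUR, NDRIVE, NFIXED
from .geometry import ShellGrid, build_grid
from .parameters import Parameters

__all__ = ["Model", "StateView", "state_size"]

DEFAULT_N_SHELLS = 20
DEFAULT_CELL_RADIUS = 10.0  # um


def state_size(n_shells: int) -> int:
    return _core.nstate(n_shells)


@dataclass
class StateView:
    """Named read access into a packed state vector."""

    y: np.ndarray
    n_shells: int

    @property
    def v(self) -> float:
        return float(self.y[_core.IV])

    @property
    def nai(self) -> float:
        return float(self.y[_core.INAI])

    @property
    def ki(self) -> float:
        return float(self.y[_core.IKI])

    @property
    def ca_sr(self) -> float:
        return float(self.y[_core.ICASR])

    @property
    def ca(self) -> np.ndarray:
        n = self.n_shells
        return self.y[NFIXED + 3 * n:NFIXED + 4 * n]

    @property
    def ryr_armed(self) -> np.ndarray:
        n = self.n_shells
        return self.y[NFIXED + n:NFIXED + 2 * n]

    @property
    def ryr_activation(self) -> np.ndarray:
        return self.y[NFIXED:NFIXED + self.n_shells]

    @property
    def ca_sl(self) -> float:
        return float(self.ca[-1])

    @property
    def gates(self) -> np.ndarray:
        return self.y[1:14]

    def buffer_bound(self, species: int) -> np.ndarray:
        n = self.n_shells
        o = NFIXED + (4 + species) * n
        return self.y[o:o + n]


class Model:
    """The spatially resolved hiPSC-CM cell model.

    Couples the sarcolemmal current inventory (I_Na, I_CaL, I_to, I_Kr,
    I_Ks, I_K1, I_f, backgrounds, NCX, NKA, PMCA) to a radially discretized
    cytosol with central + peripheral SR Ca2+ release ("fire-diffuse-fire").
    Instances are immutable in practice: `scale` and the variant transforms
    return modified copies.
    """

    def __init__(self, params: Parameters | None = None,
                 n_shells: int = DEFAULT_N_SHELLS,
                 cell_radius: float = DEFAULT_CELL_RADIUS,
                 grid: ShellGrid | None = None):
        self.params = params if params is not None else Parameters()
        self.grid = grid if grid is not None else build_grid(cell_radius, n_shells)
        self.applied_variants: tuple = ()
        self._p = self.params.to_array()

    # -- construction helpers -------------------------------------------
    def copy(self, params: Parameters | None = None) -> "Model":
        m = Model(params if params is not None else self.params, grid=self.grid)
        m.applied_variants = self.applied_variants
        return m

    def scale(self, target: str, factor: float) -> "Model":
        """Return a copy with the named pathway's maximum rate scaled."""
        return self.copy(self.params.scaled(target, factor))

    def with_blocks(self, blocks: dict) -> "Model":
        """Apply fractional blocks, e.g. ``{"NCX": 0.9}`` for a 90% block."""
        m = self
        for target, frac in blocks.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"block fraction for {target} must be in [0,1], got {frac}")
            m = m.scale(target, 1.0 - frac)
        return m

    def __eq__(self, other) -> bool:
        return (isinstance(other, Model) and self.params == other.params
                and self.grid.n_shells == other.grid.n_shells
                and self.grid.cell_radius == other.grid.cell_radius)

    # -- state vectors ----------------------------------------------------
    @property
    def n_states(self) -> int:
        return state_size(self.grid.n_shells)

    def view(self, y: np.ndarray) -> StateView:
        return StateView(y, self.grid.n_shells)

    def initial_state(self) -> np.ndarray:
        """A plausible quiescent starting point (not a steady state)."""
        n = self.grid.n_shells
        y = np.zeros(self.n_states)
        y[_core.IV] = -70.0
        # gates at their resting steady-state values
        drive = self.default_drive()
        y[_core.INAI] = 8.0
        y[_core.IKI] = 140.0
        y[_core.ICASR] = 0.3
        ca0 = 1.0e-4
        p = self.params
        y[NFIXED:NFIXED + n] = 1e-4            # RyR activation gates
        y[NFIXED + n:NFIXED + 2 * n] = 1.0     # armed flags
        y[NFIXED + 2 * n:NFIXED + 3 * n] = 0.0  # state timers
        y[NFIXED + 3 * n:NFIXED + 4 * n] = ca0
        y[NFIXED + 4 * n:NFIXED + 5 * n] = p.buf1_tot * ca0 / (ca0 + p.buf1_koff / p.buf1_kon)
        y[NFIXED + 5 * n:NFIXED + 6 * n] = p.buf2_tot * ca0 / (ca0 + p.buf2_koff / p.buf2_kon)
        if p.fluo_tot > 0:
            y[NFIXED + 6 * n:NFIXED + 7 * n] = p.fluo_tot * ca0 / (ca0 + p.fluo_koff / p.fluo_kon)
        dy, xinf, xtau = self._eval(y, drive)
        for i in range(1, 14):
            y[i] = xinf[i]
        return y

    def default_drive(self) -> np.ndarray:
        d = np.zeros(NDRIVE)
        d[_core.D_FORCE_C] = -1.0
        d[_core.D_FORCE_P2] = -1.0
        d[_core.D_FORCE_P4] = -1.0
        d[_core.D_FORCE_ALL] = -1.0
        return d

    # -- physics access ---------------------------------------------------
    def _eval(self, y, drive):
        g = self.grid
        dy = np.zeros(self.n_states)
        xinf = np.zeros(self.n_states)
        xtau = np.zeros(self.n_states)
        cur = np.zeros(NCUR)
        _core.rhs(np.asarray(y, dtype=float).copy(), self._p, g.centers, g.volumes,
                  g.areas, g.dr, g.site_indices[0], g.site_indices[1],
                  g.central_indices.astype(np.int64), drive, dy, xinf, xtau, cur)
        self._last_cur = cur
        return dy, xinf, xtau

    def rhs(self, y: np.ndarray, drive: np.ndarray | None = None) -> np.ndarray:
        """State derivative at ``y`` (pure; identical inputs give identical output)."""
        if drive is None:
            drive = self.default_drive()
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("non-finite model state passed to rhs")
        dy, _, _ = self._eval(y, drive)
        return dy

    def currents(self, y: np.ndarray, drive: np.ndarray | None = None) -> dict:
        """All membrane currents (pA/pF) and SR fluxes (mM/ms) at state ``y``."""
        if drive is None:
            drive = self.default_drive()
        self._eval(y, drive)
        return dict(zip(CUR_NAMES, self._last_cur))

    def gating_rates(self, y: np.ndarray):
        """(x_inf, tau) per state slot; tau == 0 marks non-gate entries."""
        _, xinf, xtau = self._eval(y, self.default_drive())
        return xinf, xtau

    # -- volumes ----------------------------------------------------------
    @property
    def vol_cyto(self) -> float:
        """Ca-accessible cytosolic volume, um^3."""
        return float(self.params.vol_cyto_frac * self.grid.volumes.sum())

    @property
    def vol_sr(self) -> float:
        return float(self.params.vol_sr_frac * self.grid.volumes.sum())

    def bulk_ca(self, y: np.ndarray) -> float:
        """Volume-weighted cytosolic free Ca (mM)."""
        n = self.grid.n_shells
        w = self.params.vol_cyto_frac * self.grid.volumes
        return float(np.dot(y[NFIXED + 3 * n:NFIXED + 4 * n], w) / w.sum())

    def total_cell_ca(self, y: np.ndarray) -> float:
        """Total Ca content (free + buffered + SR), as moles / cytosolic volume (mM)."""
        n = self.grid.n_shells
        w = self.params.vol_cyto_frac * self.grid.volumes
        free = np.dot(y[NFIXED + 3 * n:NFIXED + 4 * n], w)
        bound = 0.0
        for s in range(3):
            o = NFIXED + (4 + s) * n
            bound += np.dot(y[o:o + n], w)
        casr = y[_core.ICASR]
        p = self.params
        csq_bound = p.csq_tot * casr / (p.csq_kd + casr)
        sr = (casr + csq_bound) * self.vol_sr
        return float((free + bound + sr) / w.sum())

    # -- fingerprints ------------------------------------------------------
    def params_hash(self) -> str:
        blob = json.dumps(self.params.to_dict(), sort_keys=True).encode()
        blob += f"|{self.grid.n_shells}|{self.grid.cell_radius}".encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_packaged_steady_state() -> dict:
    """The shipped control 1 Hz paced steady-state snapshot."""
    ref = importlib.resources.files("ipsccm") / "data" / "steady_state_1hz.json"
    return json.loads(ref.read_text())
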
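"""Whole-cell simulation driver: stimuli, integration, steady states."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from ._core import CUR_NAMES, NCUR
from .model import Model

__all__ = [
    "SolverConfig", "StimulusSpec", "Trace", "SolverError", "run_segments",
    "simulate", "find_threshold", "run_to_steady_state", "SteadyStateResult",
]


class SolverError(RuntimeError):
    """Integration fault; carries the last valid state and time."""

    def __init__(self, msg, t=None, state=None):
        super().__init__(msg)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class SolverConfig:
    """Time-stepping controls (ms).

    The step shrinks from ``dt_max`` in proportion to |dV/dt| and to the
    fastest relative Ca rate, and is capped at ``dt_pulse`` while a stimulus
    pulse is on so 0.5 ms pulses are never stepped over.
    """

    dt_min: float = 0.005
    dt_max: float = 0.20
    dt_pulse: float = 0.02
    rec_dt: float = 0.5  # output sampling interval, ms


@dataclass(frozen=True)
class StimulusSpec:
    """Excitation mode: free-running or field-stimulated.

    Paced pulses are rectangular, ``pulse_duration`` ms long, with amplitude
    ``amplitude_multiple`` x threshold (resolved per model unless an explicit
    ``amplitude`` in pA/pF is given).
    """

    mode: str = "spontaneous"
    frequency: float = 1.0
    pulse_duration: float = 0.5
    amplitude_multiple: float = 1.5
    amplitude: float | None = None

    def __post_init__(self):
        if self.mode not in ("spontaneous", "paced"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.mode == "paced" and self.frequency <= 0:
            raise ValueError("paced mode needs frequency > 0")
        if self.amplitude is None and self.amplitude_multiple <= 1:
            raise ValueError("amplitude_multiple must exceed 1")


@dataclass
class Trace:
    """Uniformly sampled output of one simulation (time in ms)."""

    time: np.ndarray
    y: np.ndarray                 # (nt, n_states)
    currents: np.ndarray          # (nt, NCUR)
    stim_times: np.ndarray
    n_shells: int
    ca_weights: np.ndarray        # shell volume weights for bulk averaging
    meta: dict = field(default_factory=dict)

    @property
    def v(self) -> np.ndarray:
        return self.y[:, _core.IV]

    @property
    def ca_shells(self) -> np.ndarray:
        n = self.n_shells
        return self.y[:, _core.NFIXED + 3 * n:_core.NFIXED + 4 * n]

    @property
    def ryr_armed(self) -> np.ndarray:
        n = self.n_shells
        return self.y[:, _core.NFIXED + n:_core.NFIXED + 2 * n]

    @property
    def ca_bulk(self) -> np.ndarray:
        w = self.ca_weights / self.ca_weights.sum()
        return self.ca_shells @ w

    @property
    def ca_sr(self) -> np.ndarray:
        return self.y[:, _core.ICASR]

    def current(self, name: str) -> np.ndarray:
        return self.currents[:, CUR_NAMES.index(name)]

    def current_dict(self) -> dict:
        return {n: self.currents[:, i] for i, n in enumerate(CUR_NAMES)}

    def window(self, t0: float, t1: float) -> "Trace":
        m = (self.time >= t0 - 1e-9) & (self.time <= t1 + 1e-9)
        return Trace(self.time[m], self.y[m], self.currents[m],
                     self.stim_times[(self.stim_times >= t0) & (self.stim_times <= t1)],
                     self.n_shells, self.ca_weights, dict(self.meta))


def _grid_args(model: Model):
    g = model.grid
    return (g.centers, g.volumes, g.areas, g.dr,
            g.site_indices[0], g.site_indices[1],
            g.central_indices.astype(np.int64))


def _segment(model, y, t0, t1, drive, rec, out_y, out_c, solver, pulse_on=False):
    dt_max = solver.dt_pulse if pulse_on else solver.dt_max
    t, nst = _core.integrate(y, t0, t1, model._p, *_grid_args(model), drive,
                             solver.dt_min, dt_max, rec, out_y, out_c)
    if nst < 0:
        raise SolverError(f"non-finite state at t = {t:.3f} ms", t=t, state=y.copy())
    return int(nst)


def simulate(model: Model, stimulus: StimulusSpec | None = None,
             duration: float = 260.0, record_last: float | None = None,
             y0: np.ndarray | None = None, solver: SolverConfig | None = None,
             drive_extra: dict | None = None) -> Trace:
    """Run the model for ``duration`` seconds and return a sampled Trace.

    ``record_last`` limits dense output (at ``solver.rec_dt``) to the final
    window of that many seconds; by default the whole run is recorded.
    Identical inputs produce identical traces (the integrator is
    deterministic).
    """
    stimulus = stimulus or StimulusSpec()
    solver = solver or SolverConfig()
    y = np.array(model.initial_state() if y0 is None else y0, dtype=float)
    dur_ms = duration * 1000.0
    rec_start = 0.0 if record_last is None else max(0.0, dur_ms - record_last * 1000.0)
    rec = np.arange(rec_start, dur_ms + solver.rec_dt * 0.5, solver.rec_dt)
    if dur_ms == 0.0:
        rec = np.array([0.0])
    out_y = np.empty((rec.size, y.size))
    out_c = np.empty((rec.size, NCUR))

    drive = model.default_drive()
    if drive_extra:
        for k, v in drive_extra.items():
            drive[k] = v
    nsteps = 0

    if dur_ms == 0.0:
        _segment(model, y, 0.0, 0.0, drive, rec, out_y, out_c, solver)
        return Trace(rec, out_y, out_c, np.array([]), model.grid.n_shells,
                     model.params.vol_cyto_frac * model.grid.volumes,
                     {"n_steps": 0, "final_state": y})

    if stimulus.mode == "spontaneous":
        nsteps += _segment(model, y, 0.0, dur_ms, drive, rec, out_y, out_c, solver)
        stim_times = np.array([])
    else:
        amp = stimulus.amplitude
        if amp is None:
            thr = find_threshold(model, y0=y, pulse_duration=stimulus.pulse_duration,
                                 solver=solver)
            if not np.isfinite(thr):
                raise SolverError("model is inexcitable at the search bound")
            amp = stimulus.amplitude_multiple * thr
        period = 1000.0 / stimulus.frequency
        pd = stimulus.pulse_duration
        starts = np.arange(0.0, dur_ms - 1e-6, period)
        stim_times = starts
        d_on = drive.copy()
        d_on[_core.D_STIM] = -amp
        t = 0.0
        for t_on in starts:
            if t_on > t:  # gap before this pulse (empty only at t = 0)
                k0, k1 = np.searchsorted(rec, [t, t_on - 1e-9])
                nsteps += _segment(model, y, t, t_on, drive, rec[k0:k1],
                                   out_y[k0:k1], out_c[k0:k1], solver)
                t = t_on
            t_off = min(t_on + pd, dur_ms)
            k0, k1 = np.searchsorted(rec, [t, t_off - 1e-9])
            nsteps += _segment(model, y, t, t_off, d_on, rec[k0:k1],
                               out_y[k0:k1], out_c[k0:k1], solver, pulse_on=True)
            t = t_off
        if t < dur_ms:
            k0, k1 = np.searchsorted(rec, [t, dur_ms + 1e-9])
            nsteps += _segment(model, y, t, dur_ms, drive, rec[k0:k1],
                               out_y[k0:k1], out_c[k0:k1], solver)

    return Trace(rec, out_y, out_c, stim_times, model.grid.n_shells,
                 model.params.vol_cyto_frac * model.grid.volumes,
                 {"n_steps": nsteps, "final_state": y,
                  "stim_amplitude": None if stimulus.mode == "spontaneous" else amp})


def find_threshold(model: Model, y0: np.ndarray | None = None,
                   pulse_duration: float = 0.5,
                   solver: SolverConfig | None = None,
                   upper: float = 512.0) -> float:
    """Minimal pulse amplitude (pA/pF) that elicits an AP from a diastolic state.

    "Elicits" means the membrane overshoots 0 mV within 100 ms of the pulse.
    Bisection runs until the bracket is narrower than 1%; the returned value
    is the eliciting (upper) edge.  Returns ``inf`` if even ``upper`` fails
    (inexcitable flag).
    """
    solver = solver or SolverConfig()
    y0 = model.initial_state() if y0 is None else np.asarray(y0, dtype=float)

    def elicits(amp: float) -> bool:
        y = y0.copy()
        rec = np.arange(0.0, 100.0, 0.5)
        out_y = np.empty((rec.size, y.size))
        out_c = np.empty((rec.size, NCUR))
        d_on = model.default_drive()
        d_on[_core.D_STIM] = -amp
        _segment(model, y, 0.0, pulse_duration, d_on, rec[:0], out_y[:0], out_c[:0],
                 solver, pulse_on=True)
        _segment(model, y, pulse_duration, 100.0, model.default_drive(), rec[1:],
                 out_y[1:], out_c[1:], solver)
        return bool(np.max(out_y[1:, _core.IV]) > 0.0)

    lo, hi = 0.0, None
    amp = 1.0
    while amp <= upper:
        if elicits(amp):
            hi = amp
            break
        lo = amp
        amp *= 2.0
    if hi is None:
        return float("inf")
    while (hi - lo) > 0.01 * hi:
        mid = 0.5 * (lo + hi)
        if elicits(mid):
            hi = mid
        else:
            lo = mid
    return hi


def run_segments(model: Model, segments, y0: np.ndarray,
                 solver: SolverConfig | None = None,
                 record_from: float = 0.0) -> Trace:
    """Integrate a protocol given as explicit (t0, t1, drive) segments (ms).

    ``drive`` entries may be dicts of {drive_index: value} overlaid on the
    model's default drive.  Recording starts at ``record_from`` (ms) on the
    solver's rec_dt grid.  Used by clamp, caffeine, injection, ramp and
    CPVT protocols.
    """
    solver = solver or SolverConfig()
    y = np.array(y0, dtype=float)
    t_end = segments[-1][1]
    rec = np.arange(record_from, t_end + solver.rec_dt * 0.5, solver.rec_dt)
    out_y = np.empty((rec.size, y.size))
    out_c = np.empty((rec.size, NCUR))
    nsteps = 0
    base = model.default_drive()
    for (t0, t1, dv) in segments:
        d = base.copy()
        if dv:
            for k, v in dv.items():
                d[k] = v
        k0, k1 = np.searchsorted(rec, [t0, t1 - 1e-9])
        if t1 >= t_end - 1e-9:
            k1 = rec.size
        pulse_on = bool(dv) and dv.get(_core.D_STIM, 0.0) != 0.0
        nsteps += _segment(model, y, t0, t1, d, rec[k0:k1],
                           out_y[k0:k1], out_c[k0:k1], solver, pulse_on=pulse_on)
    return Trace(rec, out_y, out_c, np.array([]), model.grid.n_shells,
                 model.params.vol_cyto_frac * model.grid.volumes,
                 {"n_steps": nsteps, "final_state": y})


@dataclass
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    apd90_spread: float
    cat_spread: float
    trace: Trace | None = None
    threshold: float | None = None


def run_to_steady_state(model: Model, stimulus: StimulusSpec | None = None,
                        duration: float = 260.0,
                        y0: np.ndarray | None = None,
                        solver: SolverConfig | None = None,
                        n_check_cycles: int = 10) -> SteadyStateResult:
    """Integrate toward the periodic regime and assert cycle-to-cycle stability.

    Steady state is accepted when APD90 and CaT amplitude vary by < 0.5%
    across the last ``n_check_cycles`` analyzed cycles (an alternating 2:2
    sequence fails this).  Non-convergence sets a flag; it never raises.
    """
    from .biomarkers import per_cycle_biomarkers

    stimulus = stimulus or StimulusSpec(mode="paced", frequency=1.0)
    solver = solver or SolverConfig()
    window = max(12.0, (n_check_cycles + 2) / max(stimulus.frequency, 0.5))
    tr = simulate(model, stimulus, duration=duration, record_last=window,
                  y0=y0, solver=solver)
    cyc = per_cycle_biomarkers(tr)
    apds = np.array([c.apd90 for c in cyc if c.apd90 is not None])
    cats = np.array([c.cat_amp for c in cyc if c.cat_amp is not None])

    def spread(x):
        x = x[-n_check_cycles:]
        if x.size < 3 or np.mean(x) == 0:
            return np.inf
        return float((np.max(x) - np.min(x)) / abs(np.mean(x)))

    s_apd, s_cat = spread(apds), spread(cats)
    converged = s_apd < 0.005 and s_cat < 0.005
    return SteadyStateResult(state=tr.meta["final_state"], converged=converged,
                             apd90_spread=s_apd, cat_spread=s_cat, trace=tr,
                             threshold=tr.meta.get("stim_amplitude"))
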
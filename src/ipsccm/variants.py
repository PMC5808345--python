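"""Disease-variant transformations: Brugada, long-QT type 2, CPVT-like.

BrS and LQT2 are deterministic parameter transforms; the CPVT-like condition
is a stochastic protocol forcing randomly timed RyR openings and quantifying
the resulting membrane-voltage deviations (arrhythmogenic coupling
efficiency, ACE) against a paired control run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .biomarkers import BiomarkerSet, ace_metric, mean_biomarkers, per_cycle_biomarkers
from .model import Model
from .protocols import ProtocolResult, control_state
from .simulate import SolverConfig, run_segments

__all__ = ["VariantSpec", "apply_brs", "apply_lqt2", "cpvt_run", "VariantError"]


class VariantError(RuntimeError):
    """Raised when a variant is applied to a model that already carries it."""


#: Brugada transformation (Na_v beta1b / H162P): amplitude -52%, availability
#: curve shifted 6.7 mV toward negative potentials, slow/fast recovery from
#: inactivation slowed by 75% and 46%.
BRS_AMPLITUDE_FACTOR = 0.52
BRS_AVAIL_SHIFT_MV = 6.7
BRS_SLOW_RECOVERY_FACTOR = 1.75
BRS_FAST_RECOVERY_FACTOR = 1.46

#: LQT2 (c.A2987T KCNH2): I_Kr conductance reduced by 33%.
LQT2_GKR_FACTOR = 0.67


@dataclass(frozen=True)
class VariantSpec:
    """Configuration of the stochastic CPVT-like protocol."""

    name: str = "CPVT"
    event_rate: float = 0.5       # forced openings per second
    open_probability: float = 1.0
    open_duration: float = 20.0   # ms
    seed: int = 0
    duration: float = 30.0        # s, total simulated time

    def __post_init__(self):
        if not 0.0 <= self.open_probability <= 1.0:
            raise ValueError("open_probability must be in [0, 1]")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")


def apply_brs(model: Model) -> Model:
    """Brugada-syndrome I_Na loss-of-function transform (idempotency-guarded)."""
    if "BrS" in model.applied_variants:
        raise VariantError("BrS variant already applied to this model")
    p = model.params
    out = model.copy(p.replace(
        g_na=p.g_na * BRS_AMPLITUDE_FACTOR,
        na_avail_shift=p.na_avail_shift + BRS_AVAIL_SHIFT_MV,
        na_tauj_scale=p.na_tauj_scale * BRS_SLOW_RECOVERY_FACTOR,
        na_tauh_scale=p.na_tauh_scale * BRS_FAST_RECOVERY_FACTOR,
    ))
    out.applied_variants = model.applied_variants + ("BrS",)
    return out


def apply_lqt2(model: Model) -> Model:
    """Long-QT-2 transform: I_Kr conductance x 0.67 (idempotency-guarded)."""
    if "LQT2" in model.applied_variants:
        raise VariantError("LQT2 variant already applied to this model")
    out = model.scale("I_Kr", LQT2_GKR_FACTOR)
    out.applied_variants = model.applied_variants + ("LQT2",)
    return out


def draw_events(spec: VariantSpec, rng: np.random.Generator | None = None):
    """Poisson-timed forced-opening events: list of (t_ms, site, duration_ms)."""
    rng = rng or np.random.default_rng(spec.seed)
    events = []
    t = 0.0
    dur_ms = spec.duration * 1000.0
    if spec.event_rate <= 0:
        return events
    while True:
        t += rng.exponential(1000.0 / spec.event_rate)
        if t >= dur_ms:
            break
        site = int(rng.integers(0, 3))
        events.append((t, site, spec.open_duration))
    return events


_SITE_DRIVE = {0: _core.D_FORCE_C, 1: _core.D_FORCE_P2, 2: _core.D_FORCE_P4}


def cpvt_run(model: Model, spec: VariantSpec | None = None,
             y0: np.ndarray | None = None,
             solver: SolverConfig | None = None) -> ProtocolResult:
    """CPVT-like condition: randomly timed forced RyR openings, paired control.

    Each event forces the open probability of one randomly chosen release
    location (central region or one of the peripheral sites) to
    ``spec.open_probability`` for ``spec.open_duration`` ms.  The unpaced
    run is compared with an identical run without events; the ACE score is
    the mean absolute voltage deviation (mV).
    """
    spec = spec or VariantSpec()
    y0 = control_state(model) if y0 is None else np.array(y0)
    rng = np.random.default_rng(spec.seed)
    events = draw_events(spec, rng)
    dur_ms = spec.duration * 1000.0

    # build piecewise drive segments around the events
    segments = []
    t = 0.0
    for (te, site, dur) in events:
        if te > t:
            segments.append((t, te, None))
        segments.append((te, min(te + dur, dur_ms),
                         {_SITE_DRIVE[site]: spec.open_probability}))
        t = min(te + dur, dur_ms)
    if t < dur_ms:
        segments.append((t, dur_ms, None))

    tr = run_segments(model, segments, y0.copy(), solver=solver)
    tr_ctrl = run_segments(model, [(0.0, dur_ms, None)], y0.copy(), solver=solver)
    ace = ace_metric(tr.time, tr.v, tr_ctrl.time, tr_ctrl.v)

    cyc = per_cycle_biomarkers(tr)
    res = ProtocolResult("cpvt", tr, mean_biomarkers(cyc), cyc)
    res.payload["events"] = [
        {"time_ms": te, "site_index": site, "duration_ms": dur}
        for (te, site, dur) in events
    ]
    res.payload["ace_mv"] = ace
    res.payload["control_trace"] = tr_ctrl
    res.payload["seed"] = spec.seed
    return res
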
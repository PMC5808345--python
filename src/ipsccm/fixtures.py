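"""Analytic waveform generator for testing the measurement layer.

Produces AP- and CaT-like waveforms whose biomarkers are known in closed
form, so the extraction code can be validated without running the cell
model.  Supported families: trapezoid AP, triangle AP, exponential Ca
transient, and periodic pulse trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomarkers import BiomarkerSet

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    family: str = "triangle_ap"   # triangle_ap | trapezoid_ap | exp_cat | pulse_train
    baseline: float = -75.0       # mV (or mM for exp_cat)
    peak: float = 25.0
    rise_ms: float = 2.0
    fall_ms: float = 300.0        # triangle: linear fall time; trapezoid: plateau
    plateau_ms: float = 200.0     # trapezoid only
    tail_ms: float = 5.0          # trapezoid fall edge
    tau_ms: float = 400.0         # exp_cat decay constant
    period_ms: float = 1000.0
    n_cycles: int = 5
    dt_ms: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.family not in ("triangle_ap", "trapezoid_ap", "exp_cat", "pulse_train"):
            raise ValueError(f"unknown fixture family {self.family!r}")


def _one_triangle(tt, spec):
    """Piecewise-linear AP: rise then linear fall back to baseline."""
    amp = spec.peak - spec.baseline
    y = np.full_like(tt, spec.baseline)
    up = (tt >= 0) & (tt < spec.rise_ms)
    y[up] = spec.baseline + amp * tt[up] / spec.rise_ms
    dn = (tt >= spec.rise_ms) & (tt < spec.rise_ms + spec.fall_ms)
    y[dn] = spec.peak - amp * (tt[dn] - spec.rise_ms) / spec.fall_ms
    return y


def _one_trapezoid(tt, spec):
    amp = spec.peak - spec.baseline
    y = np.full_like(tt, spec.baseline)
    up = (tt >= 0) & (tt < spec.rise_ms)
    y[up] = spec.baseline + amp * tt[up] / spec.rise_ms
    t1 = spec.rise_ms + spec.plateau_ms
    y[(tt >= spec.rise_ms) & (tt < t1)] = spec.peak
    dn = (tt >= t1) & (tt < t1 + spec.tail_ms)
    y[dn] = spec.peak - amp * (tt[dn] - t1) / spec.tail_ms
    return y


def generate_fixture(spec: FixtureSpec, seed: int | None = None):
    """Build the waveform and its ground-truth biomarkers.

    Returns ``(time_ms, values, truth)`` where ``truth`` is a BiomarkerSet
    with the closed-form values implied by the shape constants.  With
    ``noise_sd > 0`` Gaussian noise is added (seeded, reproducible).
    """
    total = spec.period_ms * spec.n_cycles
    time = np.arange(0.0, total, spec.dt_ms)
    y = np.full_like(time, spec.baseline)
    truth = BiomarkerSet()
    amp = spec.peak - spec.baseline

    if spec.family in ("triangle_ap", "trapezoid_ap", "pulse_train"):
        one = _one_trapezoid if spec.family != "triangle_ap" else _one_triangle
        if spec.family == "pulse_train":
            def one(tt, s):  # square pulses of width plateau_ms, offset so
                # the first rising edge is interior to the record
                yy = np.full_like(tt, s.baseline)
                yy[(tt >= 50.0) & (tt < 50.0 + s.plateau_ms)] = s.peak
                return yy
        for k in range(spec.n_cycles):
            tt = time - k * spec.period_ms
            seg = one(tt, spec)
            y = np.maximum(y, seg)
        truth.mdp = spec.baseline
        truth.ap_peak = spec.peak
        truth.ap_amp = amp
        truth.cycle_length = spec.period_ms
        if spec.family == "triangle_ap":
            # linear fall: APDx measured from onset (= end of rise, where
            # dV/dt is maximal over the rise) to the x% repolarization point
            truth.apd30 = spec.rise_ms / 2 + 0.30 * spec.fall_ms
            truth.apd90 = spec.rise_ms / 2 + 0.90 * spec.fall_ms
            truth.ap_tri = (truth.apd90 - truth.apd30) / truth.apd90
        elif spec.family == "trapezoid_ap":
            truth.apd30 = spec.rise_ms / 2 + spec.plateau_ms + 0.30 * spec.tail_ms
            truth.apd90 = spec.rise_ms / 2 + spec.plateau_ms + 0.90 * spec.tail_ms
            truth.ap_tri = (truth.apd90 - truth.apd30) / truth.apd90
        else:
            truth.apd30 = truth.apd90 = spec.plateau_ms
            truth.ap_tri = 0.0
    else:  # exp_cat
        for k in range(spec.n_cycles):
            tt = time - k * spec.period_ms
            m = (tt >= 0)
            rise = np.clip(tt / spec.rise_ms, 0, 1)
            y = np.maximum(y, np.where(
                m, spec.baseline + amp * rise * np.exp(-np.maximum(tt - spec.rise_ms, 0.0) / spec.tau_ms),
                spec.baseline))
        truth.ca_dias = spec.baseline
        truth.cat_amp = amp
        truth.cat_decay_tau = spec.tau_ms
        truth.cycle_length = spec.period_ms

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.size)
    return time, y, truth
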
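"""AP and Ca-transient biomarker extraction.

Biomarkers measured per MDP-to-MDP cycle: MDP, AP peak/amplitude, APD30,
APD90, triangulation (APD90 - APD30)/APD90, maximum diastolic depolarization
rate (DDR), diastolic Ca, CaT amplitude and decay time constant.  All AP
durations are referenced to the AP onset (time of maximum dV/dt), which
keeps spontaneous and paced cycles comparable; repolarization crossings are
located by linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BiomarkerSet", "segment_aps", "ap_biomarkers", "cat_biomarkers",
    "per_cycle_biomarkers", "mean_biomarkers", "monotonic_max_freq", "ace_metric",
]

#: biomarkers used in sensitivity/database analyses (the standard eight)
SENSITIVITY_BIOMARKERS = ("mdp", "ap_amp", "ddr_trimax", "ap_tri", "apd30",
                          "apd90", "ca_dias", "cat_amp")


@dataclass
class BiomarkerSet:
    mdp: float | None = None            # mV
    ap_peak: float | None = None        # mV
    ap_amp: float | None = None         # mV
    apd30: float | None = None          # ms
    apd90: float | None = None          # ms
    ap_tri: float | None = None         # (APD90 - APD30)/APD90
    ddr_trimax: float | None = None     # mV/ms
    ca_dias: float | None = None        # mM
    cat_amp: float | None = None        # mM
    cat_decay_tau: float | None = None  # ms
    cycle_length: float | None = None   # ms
    onset_time: float | None = None     # ms, absolute
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mdp", "ap_peak", "ap_amp", "apd30", "apd90", "ap_tri",
            "ddr_trimax", "ca_dias", "cat_amp", "cat_decay_tau", "cycle_length")}


def segment_aps(time: np.ndarray, v: np.ndarray,
                prominence: float = 30.0) -> list:
    """Split a voltage trace into complete MDP-to-MDP cycle windows.

    Returns a list of ``(i0, i1, ipeak)`` sample-index triples; empty if
    fewer than two APs are present (no complete cycle).
    """
    time = np.asarray(time, float)
    v = np.asarray(v, float)
    if v.size < 5 or np.ptp(v) < prominence:
        return []
    peaks, _ = find_peaks(v, prominence=prominence, plateau_size=(1, None))
    if peaks.size < 2:
        return []
    mdps = []
    gap = float(np.median(np.diff(peaks)))
    # leading/trailing diastoles count as MDPs when long enough to hold one
    if peaks[0] >= 0.5 * gap:
        mdps.append(int(np.argmin(v[:peaks[0]])))
    for a, b in zip(peaks[:-1], peaks[1:]):
        mdps.append(a + int(np.argmin(v[a:b])))
    if v.size - 1 - peaks[-1] >= 0.5 * gap:
        mdps.append(peaks[-1] + int(np.argmin(v[peaks[-1]:])))
    windows = []
    for k in range(len(mdps) - 1):
        i0, i1 = mdps[k], mdps[k + 1]
        ipk = i0 + int(np.argmax(v[i0:i1 + 1]))
        if v[ipk] - max(v[i0], v[i1]) < prominence * 0.5:
            continue  # no full AP inside this window
        windows.append((i0, i1, ipk))
    return windows


def _cross_time(time, x, thr, start, stop, falling=True):
    """Interpolated time of the first threshold crossing in [start, stop)."""
    seg = x[start:stop]
    if falling:
        below = seg < thr
    else:
        below = seg > thr
    idx = np.nonzero(below)[0]
    if idx.size == 0 or idx[0] == 0:
        return None
    i = start + idx[0]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(time[i])
    f = (thr - x0) / (x1 - x0)
    return float(time[i - 1] + f * (time[i] - time[i - 1]))


def _smooth(x, time, width_ms=5.0):
    dt = np.median(np.diff(time))
    w = max(1, int(round(width_ms / dt)))
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def ap_biomarkers(time: np.ndarray, v: np.ndarray, window=None) -> BiomarkerSet:
    """AP biomarkers for one complete MDP-to-MDP cycle."""
    time = np.asarray(time, float)
    v = np.asarray(v, float)
    if window is None:
        wins = segment_aps(time, v)
        if not wins:
            return BiomarkerSet(flags=["no_complete_cycle"])
        window = wins[0]
    i0, i1, ipk = window
    bm = BiomarkerSet()
    bm.cycle_length = float(time[i1] - time[i0])
    bm.mdp = float(min(v[i0], v[i1]))
    bm.ap_peak = float(v[ipk])
    bm.ap_amp = bm.ap_peak - bm.mdp

    dvdt = np.gradient(v, time)
    onset = i0 + int(np.argmax(dvdt[i0:ipk + 1]))
    bm.onset_time = float(time[onset])

    for frac, name in ((0.30, "apd30"), (0.90, "apd90")):
        thr = bm.ap_peak - frac * bm.ap_amp
        tc = _cross_time(time, v, thr, ipk, i1 + 1, falling=True)
        if tc is None:
            bm.flags.append(f"{name}_unreached")
        else:
            setattr(bm, name, tc - bm.onset_time)
    if bm.apd90 is not None and bm.apd30 is not None and bm.apd90 > 0:
        bm.ap_tri = (bm.apd90 - bm.apd30) / bm.apd90

    sm = _smooth(dvdt, time)
    if onset > i0:
        bm.ddr_trimax = float(np.max(sm[i0:onset]))
    else:
        bm.ddr_trimax = 0.0
    return bm


def cat_biomarkers(time: np.ndarray, ca: np.ndarray, window=None) -> BiomarkerSet:
    """Ca-transient biomarkers for one cycle window.

    Decay tau comes from a log-linear exponential fit between 30% below the
    transient peak and the approach to diastole.
    """
    time = np.asarray(time, float)
    ca = np.asarray(ca, float)
    if window is None:
        window = (0, ca.size - 1, int(np.argmax(ca)))
    i0, i1, _ = window
    seg = ca[i0:i1 + 1]
    tseg = time[i0:i1 + 1]
    bm = BiomarkerSet()
    bm.ca_dias = float(np.min(seg))
    ipk = int(np.argmax(seg))
    peak = float(seg[ipk])
    bm.cat_amp = peak - bm.ca_dias
    d = np.diff(seg)
    if np.all(d <= 0) or np.all(d >= 0):
        if np.ptp(seg) > 0:
            bm.flags.append("monotone_ca_trace")
            bm.cat_amp = None
            bm.ca_dias = None
            return bm
    thr_hi = peak - 0.30 * bm.cat_amp
    thr_lo = bm.ca_dias + 0.05 * bm.cat_amp
    post = seg[ipk:]
    tpost = tseg[ipk:]
    lo = np.nonzero(post < thr_hi)[0]
    if lo.size:
        a = lo[0]
        under = np.nonzero(post[a:] < thr_lo)[0]
        b = a + (under[0] if under.size else post.size - a)
        if b - a >= 4:
            yy = post[a:b] - bm.ca_dias
            mask = yy > 0
            if mask.sum() >= 4:
                coeff = np.polyfit(tpost[a:b][mask], np.log(yy[mask]), 1)
                if coeff[0] < 0:
                    bm.cat_decay_tau = float(-1.0 / coeff[0])
    if bm.cat_decay_tau is None:
        bm.flags.append("cat_decay_unfit")
    return bm


def per_cycle_biomarkers(trace) -> list:
    """AP + CaT biomarkers for every complete cycle of a Trace."""
    time, v = trace.time, trace.v
    ca = trace.ca_bulk
    out = []
    for win in segment_aps(time, v):
        bm = ap_biomarkers(time, v, win)
        cm = cat_biomarkers(time, ca, win)
        bm.ca_dias = cm.ca_dias
        bm.cat_amp = cm.cat_amp
        bm.cat_decay_tau = cm.cat_decay_tau
        bm.flags += cm.flags
        out.append(bm)
    return out


def mean_biomarkers(cycles: list) -> BiomarkerSet:
    """Average the defined fields across cycles (flags are concatenated)."""
    bm = BiomarkerSet()
    for name in ("mdp", "ap_peak", "ap_amp", "apd30", "apd90", "ap_tri",
                 "ddr_trimax", "ca_dias", "cat_amp", "cat_decay_tau",
                 "cycle_length"):
        vals = [getattr(c, name) for c in cycles if getattr(c, name) is not None]
        if vals:
            setattr(bm, name, float(np.mean(vals)))
    for c in cycles:
        bm.flags += c.flags
    return bm


def monotonic_max_freq(freqs, values, direction: str) -> float:
    """Largest frequency up to which the series is strictly monotone.

    ``direction`` is "decreasing" (APD restitution) or "increasing" (FFR).
    A violation at the first step -- or an undefined value -- stops the scan,
    so a flat series returns the lowest frequency.
    """
    freqs = list(freqs)
    values = list(values)
    if len(freqs) != len(values) or not freqs:
        raise ValueError("freqs and values must be equal-length, non-empty")
    sign = -1.0 if direction == "decreasing" else 1.0
    fmax = freqs[0]
    for k in range(1, len(freqs)):
        if values[k] is None or values[k - 1] is None:
            break
        if sign * (values[k] - values[k - 1]) <= 0:
            break
        fmax = freqs[k]
    return float(fmax)


def ace_metric(time_a, v_a, time_b, v_b) -> float:
    """Arrhythmogenic coupling efficiency: mean |Delta V_m| (mV) over the window.

    Traces on different grids are linearly resampled onto the overlap of the
    two time ranges before differencing.
    """
    time_a = np.asarray(time_a, float)
    time_b = np.asarray(time_b, float)
    t0 = max(time_a[0], time_b[0])
    t1 = min(time_a[-1], time_b[-1])
    if t1 <= t0:
        raise ValueError("traces do not overlap in time")
    if time_a.size == time_b.size and np.allclose(time_a, time_b):
        grid, va, vb = time_a, np.asarray(v_a, float), np.asarray(v_b, float)
    else:
        dt = min(np.median(np.diff(time_a)), np.median(np.diff(time_b)))
        grid = np.arange(t0, t1, dt)
        va = np.interp(grid, time_a, v_a)
        vb = np.interp(grid, time_b, v_b)
    return float(np.trapezoid(np.abs(va - vb), grid) / (grid[-1] - grid[0]))
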
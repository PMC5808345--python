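"""Sensitivity analysis and population-of-models database screening.

Seven pathways are varied: the maximum conductances of I_to, I_Kr, I_K1,
I_CaL and I_Na and the maximum transport rates of SERCA and NCX.  The
sensitivity scan perturbs each by +-10% (14 runs) and correlates parameter
value with each biomarker; the database screen draws independent uniform
multipliers for all seven, simulates the three study protocols per virtual
cell, applies viability filters, and compares subpopulation parameter means
against the whole database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .biomarkers import SENSITIVITY_BIOMARKERS, mean_biomarkers, monotonic_max_freq, per_cycle_biomarkers
from .model import Model
from .protocols import (SWEEP_FREQUENCIES, apdr_ffr_sweep, control_state,
                        paced_run, spontaneous_run)
from .simulate import SolverConfig

__all__ = [
    "SENSITIVITY_PARAMETERS", "DEFAULT_RANGES", "SensitivityResult",
    "PopulationResult", "sensitivity_scan", "similarity_index",
    "sample_database", "run_database", "viability_filter",
    "subpopulation_stats", "select_ideal",
]

#: the seven varied pathways (scale-target names)
SENSITIVITY_PARAMETERS = ("I_to", "I_Kr", "I_K1", "I_CaL", "I_Na", "SERCA", "NCX")

#: database sampling ranges (multipliers of the control value); a wide,
#: literature-spread-like band shared by all seven pathways
DEFAULT_RANGES = {p: (0.25, 2.5) for p in SENSITIVITY_PARAMETERS}


@dataclass
class SensitivityResult:
    parameters: tuple
    biomarkers: tuple
    correlations: dict          # mode -> (n_param, n_biomarker) array
    design: np.ndarray          # (n_runs, n_param) multipliers
    missing: dict = field(default_factory=dict)

    def correlation(self, mode: str, parameter: str, biomarker: str) -> float:
        i = self.parameters.index(parameter)
        j = self.biomarkers.index(biomarker)
        return float(self.correlations[mode][i, j])


def _biomarker_vector(bm) -> list:
    return [getattr(bm, name) for name in SENSITIVITY_BIOMARKERS]


def sensitivity_scan(model: Model | None = None, delta: float = 0.10,
                     modes=("spontaneous", "paced"), duration: float = 60.0,
                     y0: np.ndarray | None = None,
                     solver: SolverConfig | None = None) -> SensitivityResult:
    """+-``delta`` one-at-a-time perturbation scan (2 runs per parameter).

    Correlates each parameter's multiplier with each biomarker across the
    design (Pearson).  Runs that fail to produce analyzable cycles are
    recorded as missing and dropped from the affected correlations.
    """
    model = model or Model()
    y0 = control_state(model) if y0 is None else y0
    design = []
    rows = {mode: [] for mode in modes}
    missing = {mode: [] for mode in modes}
    for ip, pname in enumerate(SENSITIVITY_PARAMETERS):
        for mult in (1.0 - delta, 1.0 + delta):
            row = np.ones(len(SENSITIVITY_PARAMETERS))
            row[ip] = mult
            design.append(row)
            m = model.scale(pname, mult)
            for mode in modes:
                try:
                    if mode == "spontaneous":
                        res = spontaneous_run(m, duration=duration,
                                              analysis_window=min(10.0, duration / 2),
                                              y0=np.array(y0), solver=solver)
                    else:
                        res = paced_run(m, duration=duration, y0=np.array(y0),
                                        solver=solver)
                    vec = _biomarker_vector(res.biomarkers)
                    if res.flags:
                        missing[mode].append((pname, mult, ",".join(res.flags)))
                except Exception as exc:  # viability failure: record, keep going
                    vec = [None] * len(SENSITIVITY_BIOMARKERS)
                    missing[mode].append((pname, mult, repr(exc)))
                rows[mode].append(vec)
    design = np.array(design)
    correlations = {}
    for mode in modes:
        mat = np.full((len(SENSITIVITY_PARAMETERS), len(SENSITIVITY_BIOMARKERS)),
                      np.nan)
        table = rows[mode]
        for j in range(len(SENSITIVITY_BIOMARKERS)):
            yv = np.array([r[j] if r[j] is not None else np.nan for r in table])
            ok = np.isfinite(yv)
            for i in range(len(SENSITIVITY_PARAMETERS)):
                x = design[ok, i]
                if ok.sum() >= 3 and np.std(x) > 0 and np.std(yv[ok]) > 0:
                    mat[i, j] = np.corrcoef(x, yv[ok])[0, 1]
                elif np.std(yv[ok]) == 0:
                    mat[i, j] = 0.0
        correlations[mode] = mat
    return SensitivityResult(SENSITIVITY_PARAMETERS, SENSITIVITY_BIOMARKERS,
                             correlations, design, missing)


def similarity_index(corr_a: np.ndarray, corr_b: np.ndarray,
                     biomarkers=("apd90", "cat_amp"),
                     all_biomarkers=SENSITIVITY_BIOMARKERS) -> float:
    """Sum of |correlation differences| for the chosen biomarkers (symmetric)."""
    corr_a = np.asarray(corr_a)
    corr_b = np.asarray(corr_b)
    if corr_a.shape != corr_b.shape:
        raise ValueError("correlation matrices must share the parameter set")
    cols = [all_biomarkers.index(b) for b in biomarkers]
    d = np.abs(corr_a[:, cols] - corr_b[:, cols])
    return float(np.nansum(d))


def sample_database(n: int = 3000, ranges: dict | None = None,
                    seed: int = 42) -> np.ndarray:
    """Independent uniform multiplier draws for the 7 varied parameters.

    I_f and I_Ks are not varied.  Reproducible for a fixed seed; returns an
    (n, 7) array ordered as SENSITIVITY_PARAMETERS.
    """
    ranges = ranges or DEFAULT_RANGES
    rng = np.random.default_rng(seed)
    cols = []
    for pname in SENSITIVITY_PARAMETERS:
        lo, hi = ranges[pname]
        cols.append(rng.uniform(lo, hi, size=n))
    return np.column_stack(cols)


def _variant_model(base: Model, mults) -> Model:
    m = base
    for pname, mult in zip(SENSITIVITY_PARAMETERS, mults):
        m = m.scale(pname, float(mult))
    return m


@dataclass
class PopulationResult:
    table: np.ndarray                  # (n, 7) multipliers
    parameters: tuple = SENSITIVITY_PARAMETERS
    spont_viable: np.ndarray | None = None
    paced_viable: np.ndarray | None = None
    spont_biomarkers: list = field(default_factory=list)
    paced_biomarkers: list = field(default_factory=list)
    apdr_max_freq: np.ndarray | None = None
    ffr_max_freq: np.ndarray | None = None
    apd90: np.ndarray | None = None
    failures: list = field(default_factory=list)

    def viable_fraction(self, mode: str):
        """Point estimate and 95% binomial (Wilson) CI of the viable fraction."""
        flags = self.spont_viable if mode == "spontaneous" else self.paced_viable
        k = int(np.sum(flags))
        n = len(flags)
        ci = stats.binomtest(k, n).proportion_ci(0.95, method="wilson")
        return k / n, (ci.low, ci.high)


def run_database(table: np.ndarray, base: Model | None = None,
                 protocols=("spontaneous", "paced", "apdr_ffr"),
                 spont_duration: float = 260.0, paced_duration: float = 260.0,
                 sweep_step_duration: float = 60.0,
                 freqs=SWEEP_FREQUENCIES,
                 solver: SolverConfig | None = None,
                 progress: bool = False) -> PopulationResult:
    """Run the study protocols for every row of the multiplier table.

    All runs start from the control 1 Hz paced steady state.  Individual
    failures are recorded per variant and never abort the batch; results are
    independent of execution order.
    """
    base = base or Model()
    y0 = control_state(base)
    n = table.shape[0]
    out = PopulationResult(np.array(table))
    out.spont_viable = np.zeros(n, bool)
    out.paced_viable = np.zeros(n, bool)
    out.apdr_max_freq = np.full(n, np.nan)
    out.ffr_max_freq = np.full(n, np.nan)
    out.apd90 = np.full(n, np.nan)
    for k in range(n):
        m = _variant_model(base, table[k])
        sbm = pbm = None
        if "spontaneous" in protocols:
            try:
                res = spontaneous_run(m, duration=spont_duration,
                                      y0=y0.copy(), solver=solver)
                sbm = res.biomarkers
                out.spont_viable[k] = _spont_viable(res)
            except Exception as exc:
                out.failures.append((k, "spontaneous", repr(exc)))
        if "paced" in protocols:
            try:
                res = paced_run(m, duration=paced_duration,
                                amplitude_multiple=2.0, y0=y0.copy(),
                                solver=solver)
                pbm = res.biomarkers
                out.paced_viable[k] = _paced_viable(res)
                if pbm.apd90 is not None:
                    out.apd90[k] = pbm.apd90
            except Exception as exc:
                out.failures.append((k, "paced", repr(exc)))
        if "apdr_ffr" in protocols:
            try:
                sw = apdr_ffr_sweep(m, freqs=freqs,
                                    step_duration=sweep_step_duration,
                                    y0=y0.copy(), solver=solver)
                out.apdr_max_freq[k] = monotonic_max_freq(
                    sw.payload["freqs_hz"], sw.payload["apd90_ms"], "decreasing")
                out.ffr_max_freq[k] = monotonic_max_freq(
                    sw.payload["freqs_hz"], sw.payload["cat_amp_mm"], "increasing")
            except Exception as exc:
                out.failures.append((k, "apdr_ffr", repr(exc)))
        out.spont_biomarkers.append(sbm)
        out.paced_biomarkers.append(pbm)
        if progress and (k + 1) % 10 == 0:
            print(f"  database: {k + 1}/{n}", flush=True)
    return out


def _spont_viable(res) -> bool:
    """Regular spontaneous rhythm: >= 3 APs in the window, overshoot > 0 mV,
    cycle-length coefficient of variation < 10%."""
    if "quiescent" in res.flags or len(res.cycles) < 3:
        return False
    cl = np.array([c.cycle_length for c in res.cycles if c.cycle_length])
    pk = np.array([c.ap_peak for c in res.cycles if c.ap_peak is not None])
    if cl.size < 3 or pk.size == 0 or np.max(pk) <= 0:
        return False
    return float(np.std(cl) / np.mean(cl)) < 0.10


def _paced_viable(res) -> bool:
    """1:1 capture over the analyzed APs, overshoot > 0 mV, no Ca overload,
    and all AP/CaT biomarkers computable."""
    if "capture_failure" in res.flags or "ca_overload" in res.flags:
        return False
    bm = res.biomarkers
    needed = (bm.apd90, bm.apd30, bm.ap_peak, bm.mdp, bm.cat_amp, bm.ca_dias)
    return all(v is not None for v in needed) and bm.ap_peak > 0


def viability_filter(result: PopulationResult, mode: str) -> np.ndarray:
    """Viability flags for the requested mode ("spontaneous" or "paced")."""
    if mode == "spontaneous":
        return result.spont_viable.copy()
    if mode == "paced":
        return result.paced_viable.copy()
    raise ValueError(f"unknown mode {mode!r}")


def subpopulation_stats(result: PopulationResult, subset: np.ndarray) -> dict:
    """Mean parameter deviation (%) of a subset vs. the whole database.

    Two-sided Welch test per parameter; p-values are withheld for subsets
    smaller than 3.
    """
    subset = np.asarray(subset, bool)
    if subset.sum() == 0:
        raise ValueError("subset is empty")
    out = {}
    for i, pname in enumerate(result.parameters):
        all_vals = result.table[:, i]
        sub_vals = result.table[subset, i]
        dev = (np.mean(sub_vals) - np.mean(all_vals)) / np.mean(all_vals) * 100.0
        if subset.sum() >= 3:
            p = float(stats.ttest_ind(sub_vals, all_vals, equal_var=False).pvalue)
        else:
            p = None
        out[pname] = {"deviation_pct": float(dev), "p_value": p,
                      "n_subset": int(subset.sum())}
    return out


def select_ideal(result: PopulationResult, apd90_window=(250.0, 300.0),
                 min_monotone_freq: float = 1.4) -> np.ndarray:
    """Variants with monotonic APDR and FFR through >= ``min_monotone_freq``
    Hz whose paced APD90 falls inside the window.  Returns an index array."""
    if result.apdr_max_freq is None:
        return np.array([], dtype=int)
    ok = ((result.apdr_max_freq >= min_monotone_freq)
          & (result.ffr_max_freq >= min_monotone_freq)
          & np.isfinite(result.apd90)
          & (result.apd90 >= apd90_window[0])
          & (result.apd90 <= apd90_window[1]))
    return np.nonzero(ok)[0]
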
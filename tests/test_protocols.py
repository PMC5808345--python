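import numpy as np
import pytest

from ipsccm import Model
from ipsccm.protocols import (apdr_ffr_sweep, block_experiment,
                              ca_injection_assay, caffeine_protocol,
                              control_state, cycle_flux_integrals,
                              ical_voltage_clamp, ncx_diastolic_ramp,
                              paced_run, spontaneous_run)


@pytest.fixture(scope="module")
def model():
    return Model()


@pytest.fixture(scope="module")
def ss(model):
    return control_state(model)


@pytest.fixture(scope="module")
def short_paced(model, ss):
    return paced_run(model, duration=20.0, y0=ss.copy())


@pytest.fixture(scope="module")
def short_spont(model, ss):
    return spontaneous_run(model, duration=25.0, analysis_window=10.0, y0=ss.copy())


def test_spontaneous_run_reports_rate(short_spont):
    assert "quiescent" not in short_spont.flags
    assert short_spont.payload["rate_bpm"] > 20.0


def test_paced_run_captures_with_regular_cycles(short_paced):
    assert "capture_failure" not in short_paced.flags
    cls = [c.cycle_length for c in short_paced.cycles if c.cycle_length]
    assert len(cls) >= 3
    assert np.ptp(cls) < 20.0  # ms; near-identical cycle lengths at 1 Hz


def test_paced_beats_have_larger_upstroke_than_spontaneous(short_paced, short_spont):
    """Accommodation: fast sodium current is far smaller when the upstroke
    arises from the slow diastolic depolarization."""
    ina_p = short_paced.trace.current("i_na").min()
    ina_s = short_spont.trace.current("i_na").min()
    assert abs(ina_p) > 2 * abs(ina_s)


def test_cycle_flux_integrals_zero_for_silent_trace(model, short_paced):
    res = short_paced
    silent = type(res)(res.name, res.trace, res.biomarkers, res.cycles)
    silent.trace = res.trace
    # zero out a copy of the recorded currents
    import copy
    tr = copy.copy(res.trace)
    tr.currents = np.zeros_like(res.trace.currents)
    silent.trace = tr
    out = cycle_flux_integrals(silent, model)
    assert out["ca_entry_total"] == 0.0
    assert out["ca_removal_ncx_forward"] == 0.0
    assert out["na_entry_total"] == 0.0


def test_block_experiment_identity_at_zero_fraction(model, ss, short_paced):
    res = block_experiment(model, "I_CaL", 0.0, duration=15.0,
                           control_dias=short_paced.biomarkers.ca_dias,
                           y0=ss.copy())
    ref = paced_run(model, duration=15.0, y0=ss.copy())
    assert res.biomarkers.apd90 == pytest.approx(ref.biomarkers.apd90, rel=1e-9)


def test_block_experiment_rejects_unknown_target(model):
    with pytest.raises(ValueError):
        block_experiment(model, "I_Kr", 0.5)


def test_serca_block_reduces_cat_amplitude(model, ss, short_paced):
    res = block_experiment(model, "SERCA", 0.9, duration=30.0,
                           control_dias=short_paced.biomarkers.ca_dias,
                           y0=ss.copy())
    ctrl_amp = short_paced.biomarkers.cat_amp
    if res.biomarkers.cat_amp is not None:
        assert res.biomarkers.cat_amp < ctrl_amp


def test_caffeine_releases_the_store(model, ss):
    res = caffeine_protocol(model, y0=ss.copy())
    assert res.payload["amplitude"] > 0
    assert res.payload["sr_content_released"] > 0.5 * model.view(ss).ca_sr


def test_caffeine_on_empty_store_gives_no_transient(model, ss):
    y = ss.copy()
    sv = model.view(y)
    y[16] = model.bulk_ca(y)  # SR collapsed to cytosolic level
    res = caffeine_protocol(model, duration=2.0, y0=y)
    assert res.payload["amplitude"] < 5e-5


def test_caffeine_decay_slows_without_ncx(model, ss):
    a = caffeine_protocol(model, duration=6.0, y0=ss.copy())
    b = caffeine_protocol(model.scale("NCX", 0.0), duration=6.0, y0=ss.copy())
    # removing the dominant efflux slows the transient decline: compare the
    # fraction of the peak remaining at the end of the window
    ca_a = a.trace.ca_bulk
    ca_b = b.trace.ca_bulk
    rem_a = (ca_a[-1] - ca_a[0]) / max(ca_a.max() - ca_a[0], 1e-12)
    rem_b = (ca_b[-1] - ca_b[0]) / max(ca_b.max() - ca_b[0], 1e-12)
    assert rem_b > rem_a


def test_injection_trivial_threshold_crossed_immediately(model, ss):
    res = ca_injection_assay(model, threshold=1e-6, settle_ms=200.0,
                             observe_ms=200.0, y0=ss.copy())
    assert np.allclose(res.payload["time_to_target_ms"], 0.0)


def test_injection_times_increase_with_depth(model, ss):
    res = ca_injection_assay(model, y0=ss.copy())
    tt = np.array(res.payload["time_to_target_ms"], dtype=float)
    ok = np.isfinite(tt)
    # causality of the inward wave: deeper shells never cross earlier
    # (simultaneous arrival of the regenerative phase allowed within 5 ms)
    assert np.all(np.diff(tt[ok]) > -5.0)


def test_injection_slower_without_ryr(model, ss):
    ctrl = ca_injection_assay(model, y0=ss.copy())
    no_ryr = ca_injection_assay(model.scale("RyR", 0.0), y0=ss.copy())
    tc = np.array(ctrl.payload["time_to_target_ms"], dtype=float)
    tn = np.array(no_ryr.payload["time_to_target_ms"], dtype=float)
    depth = np.array(ctrl.payload["depth_um"])
    deep = depth >= 2.0
    tn = np.where(np.isnan(tn), np.inf, tn)
    tc_masked = np.where(np.isnan(tc), np.inf, tc)
    assert np.all(tn[deep] >= tc_masked[deep])
    assert np.any(np.isinf(tn[deep]) | (tn[deep] > tc_masked[deep]))


def test_ical_availability_monotone(model, ss):
    res = ical_voltage_clamp(model, y0=ss.copy())
    avail = np.array(res.payload["availability"])
    assert avail[0] == pytest.approx(1.0)
    assert np.all(np.diff(avail) <= 1e-9)


def test_ical_iv_peak_in_expected_range(model, ss):
    res = ical_voltage_clamp(model, y0=ss.copy())
    steps = np.array(res.payload["iv_step_mv"])
    iv = np.array(res.payload["iv_peak_pa_per_pf"])
    v_peak = steps[int(np.argmin(iv))]
    assert -10.0 <= v_peak <= 10.0


def test_ncx_ramp_flat_target_stays_flat(model, ss):
    res = ncx_diastolic_ramp(model, duration=12.0, v_start=-78.0, v_end=-78.0,
                             y0=ss.copy())
    i = np.array(res.payload["i_ncx_diastolic"][3:])
    assert np.ptp(i) < 0.25  # pA/pF, within cycle-to-cycle variation


def test_ncx_forward_mode_hampered_at_depolarized_diastole(model, ss):
    res = ncx_diastolic_ramp(model, duration=40.0, y0=ss.copy())
    v = np.array(res.payload["v_diastolic_mv"])
    i = np.array(res.payload["i_ncx_diastolic"])
    # across the achieved diastolic range, more depolarized potentials give
    # less forward (less negative) exchanger current
    slope = np.polyfit(v, i, 1)[0]
    assert slope > 0


def test_apdr_sweep_is_deterministic(model, ss):
    a = apdr_ffr_sweep(model, freqs=(1.0, 1.4), step_duration=8.0, y0=ss.copy())
    b = apdr_ffr_sweep(model, freqs=(1.0, 1.4), step_duration=8.0, y0=ss.copy())
    assert a.payload["apd90_ms"] == b.payload["apd90_ms"]
    assert a.payload["cat_amp_mm"] == b.payload["cat_amp_mm"]


def test_apdr_sweep_flags_noncapturing_frequencies(model, ss):
    weak = model.scale("I_CaL", 0.05).scale("I_Na", 0.02)
    res = apdr_ffr_sweep(weak, freqs=(2.2,), step_duration=6.0,
                         amplitude=1.0, y0=ss.copy())
    assert res.payload["flags"][0] in ("capture_failure", "error")
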
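import numpy as np
import pytest

from ipsccm import (FixtureSpec, ace_metric, ap_biomarkers, cat_biomarkers,
                    generate_fixture, monotonic_max_freq, segment_aps)


def test_constant_trace_yields_no_cycles():
    t = np.arange(0, 5000.0, 0.5)
    assert segment_aps(t, np.full_like(t, -75.0)) == []


def test_five_pulses_give_four_complete_cycles():
    time, v, _ = generate_fixture(FixtureSpec(family="pulse_train", n_cycles=5))
    assert len(segment_aps(time, v)) == 4


@pytest.mark.parametrize("family", ["triangle_ap", "trapezoid_ap"])
def test_apd_matches_closed_form(family):
    spec = FixtureSpec(family=family)
    time, v, truth = generate_fixture(spec)
    bm = ap_biomarkers(time, v)
    assert bm.apd30 == pytest.approx(truth.apd30, abs=0.6)
    assert bm.apd90 == pytest.approx(truth.apd90, abs=0.6)
    assert bm.mdp == pytest.approx(truth.mdp, abs=1e-9)
    assert bm.ap_peak == pytest.approx(truth.ap_peak, abs=1e-6)
    assert bm.ap_amp == pytest.approx(truth.ap_amp, abs=1e-6)


def test_triangulation_formula_is_exact():
    # triangulation = (APD90 - APD30)/APD90; e.g. 500/200 ms -> 0.6
    time, v, _ = generate_fixture(FixtureSpec(family="triangle_ap"))
    got = ap_biomarkers(time, v)
    assert got.ap_tri == pytest.approx((got.apd90 - got.apd30) / got.apd90, rel=1e-12)
    assert (500.0 - 200.0) / 500.0 == 0.6


def test_square_pulse_apd30_equals_apd90():
    spec = FixtureSpec(family="pulse_train", plateau_ms=180.0)
    time, v, _ = generate_fixture(spec)
    bm = ap_biomarkers(time, v)
    assert bm.apd30 == pytest.approx(bm.apd90, abs=1.0)
    assert bm.apd90 == pytest.approx(180.0, abs=1.5)


def test_exponential_cat_decay_recovered_within_one_percent():
    spec = FixtureSpec(family="exp_cat", baseline=1e-4, peak=6e-4,
                       rise_ms=20.0, tau_ms=400.0, period_ms=2000.0)
    time, ca, truth = generate_fixture(spec)
    bm = cat_biomarkers(time[:3800], ca[:3800],
                        window=(0, 3799, int(np.argmax(ca[:3800]))))
    assert bm.cat_amp == pytest.approx(truth.cat_amp, rel=0.02)
    assert bm.cat_decay_tau == pytest.approx(400.0, rel=0.01)


def test_monotone_ca_trace_is_flagged():
    t = np.arange(0, 1000.0, 0.5)
    ca = 1e-4 + 1e-7 * t
    bm = cat_biomarkers(t, ca, window=(0, t.size - 1, t.size - 1))
    assert "monotone_ca_trace" in bm.flags


def test_time_shift_invariance():
    spec = FixtureSpec(family="triangle_ap")
    time, v, _ = generate_fixture(spec)
    a = ap_biomarkers(time, v)
    b = ap_biomarkers(time + 12345.0, v)
    assert a.apd90 == pytest.approx(b.apd90, abs=1e-9)
    assert a.apd30 == pytest.approx(b.apd30, abs=1e-9)


def test_resampling_invariance():
    coarse = FixtureSpec(family="triangle_ap", dt_ms=0.5)
    fine = FixtureSpec(family="triangle_ap", dt_ms=0.1)
    bma = ap_biomarkers(*generate_fixture(coarse)[:2])
    bmb = ap_biomarkers(*generate_fixture(fine)[:2])
    assert bma.apd90 == pytest.approx(bmb.apd90, rel=5e-3)
    assert bma.apd30 == pytest.approx(bmb.apd30, rel=5e-3)


def test_noisy_waveform_biomarkers_recoverable():
    """With 0.5 mV noise the AP biomarkers stay close to truth across seeds."""
    spec = FixtureSpec(family="triangle_ap", noise_sd=0.5)
    errs = []
    for seed in range(50):
        time, v, truth = generate_fixture(spec, seed=seed)
        bm = ap_biomarkers(time, v)
        errs.append(abs(bm.apd90 - truth.apd90))
    assert np.median(errs) < 5.0
    assert np.max(errs) < 25.0


def test_fixture_generator_deterministic_without_noise():
    a = generate_fixture(FixtureSpec(family="exp_cat"))
    b = generate_fixture(FixtureSpec(family="exp_cat"))
    assert np.array_equal(a[1], b[1])


def test_unknown_fixture_family_rejected():
    with pytest.raises(ValueError):
        FixtureSpec(family="sine")


@pytest.mark.parametrize("values,direction,expected", [
    ([300, 290, 280, 270, 260, 250, 240], "decreasing", 2.2),
    ([300, 290, 285, 290, 300, 310, 320], "decreasing", 1.4),
    ([300, 300, 300, 300, 300, 300, 300], "decreasing", 1.0),
    ([1, 2, 3, 4, 5, 6, 7], "increasing", 2.2),
    ([5, 4, 3, 2, 1, 0, -1], "increasing", 1.0),
    ([1, 2, None, 4, 5, 6, 7], "increasing", 1.2),
])
def test_monotonic_max_frequency(values, direction, expected):
    freqs = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2)
    assert monotonic_max_freq(freqs, values, direction) == expected


def test_monotonic_max_freq_validates_input():
    with pytest.raises(ValueError):
        monotonic_max_freq([1.0, 1.2], [1.0], "increasing")


def test_ace_identical_traces_zero():
    t = np.arange(0, 1000.0, 0.5)
    v = -70 + 50 * np.exp(-((t - 300) / 50.0) ** 2)
    assert ace_metric(t, v, t, v) == 0.0


def test_ace_uniform_offset_normalization():
    t = np.arange(0, 1000.0, 0.5)
    v = np.full_like(t, -70.0)
    assert ace_metric(t, v, t, v + 1.0) == pytest.approx(1.0, rel=1e-9)


def test_ace_symmetric_and_resamples():
    t1 = np.arange(0, 1000.0, 0.5)
    t2 = np.arange(0, 1000.0, 0.3)
    v1 = -70 + 30 * np.sin(t1 / 100.0)
    v2 = -70 + 30 * np.sin(t2 / 90.0)
    assert ace_metric(t1, v1, t2, v2) == pytest.approx(ace_metric(t2, v2, t1, v1),
                                                      rel=1e-9)


def test_ace_requires_overlap():
    with pytest.raises(ValueError):
        ace_metric([0, 1], [0, 0], [5, 6], [0, 0])
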
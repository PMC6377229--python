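"""Firing-rate, DSI, onset-latency and E/I-offset estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscircuit.ephys_analysis import (
    DirectionSeries,
    NoResponse,
    circular_sd_deg,
    direction_selectivity_index,
    ei_temporal_offset,
    onset_latency,
    phase_tuning,
    smooth_firing_rate,
    temporal_to_spatial_offset,
)

EIGHT = np.arange(8) * 45.0


# ---------------------------------------------------------------- rate

def test_single_spike_peak_rate():
    t, r = smooth_firing_rate([100.0], sigma_ms=25.0, dt_ms=0.5)
    peak = 1.0 / (0.025 * math.sqrt(2 * math.pi))     # 15.96 Hz
    assert r.max() == pytest.approx(peak, rel=1e-4)
    assert t[np.argmax(r)] == pytest.approx(100.0, abs=0.5)


def test_coincident_spikes_scale_linearly():
    _, r1 = smooth_firing_rate([50.0], sigma_ms=25.0, dt_ms=0.5)
    _, r5 = smooth_firing_rate([50.0] * 5, sigma_ms=25.0, dt_ms=0.5)
    assert r5.max() == pytest.approx(5 * r1.max(), rel=1e-9)


@given(st.lists(st.floats(min_value=0.0, max_value=2000.0),
                min_size=0, max_size=40))
@settings(max_examples=25, deadline=None)
def test_rate_integral_equals_spike_count(spikes):
    t, r = smooth_firing_rate(spikes, sigma_ms=25.0, dt_ms=1.0)
    integral = np.trapezoid(r, t / 1000.0)
    assert integral == pytest.approx(len(spikes), abs=max(1e-3, 1e-3 * len(spikes)))


def test_empty_spike_list_gives_zero_trace():
    _, r = smooth_firing_rate([], sigma_ms=25.0, dt_ms=1.0)
    assert np.all(r == 0.0)


# ---------------------------------------------------------------- DSI

def test_dsi_single_direction_is_one():
    series = DirectionSeries(EIGHT, np.array([7.0, 0, 0, 0, 0, 0, 0, 0]))
    res = direction_selectivity_index(series)
    assert res.dsi == pytest.approx(1.0)
    assert res.preferred_angle_deg == pytest.approx(0.0)


def test_dsi_symmetric_response_is_zero():
    res = direction_selectivity_index(DirectionSeries(EIGHT, np.full(8, 3.0)))
    assert res.dsi == pytest.approx(0.0, abs=1e-12)


def test_dsi_seven_plus_one_decomposition():
    """(2,1,...,1): the eight unit vectors cancel, leaving 1 of 9 spikes."""
    res = direction_selectivity_index(
        DirectionSeries(EIGHT, np.array([2.0, 1, 1, 1, 1, 1, 1, 1])))
    assert res.dsi == pytest.approx(1.0 / 9.0, abs=1e-12)
    assert res.preferred_angle_deg == pytest.approx(0.0, abs=1e-9)


@given(st.lists(st.floats(min_value=0.0, max_value=100.0),
                min_size=8, max_size=8),
       st.floats(min_value=0.01, max_value=50.0))
@settings(max_examples=50, deadline=None)
def test_dsi_brute_force_oracle_and_scale_invariance(r, c):
    r = np.asarray(r)
    if r.sum() <= 1e-6:      # degenerate: all-zero (or underflowing) series
        return
    res = direction_selectivity_index(DirectionSeries(EIGHT, r))
    # brute-force complex sum oracle
    z = sum(ri * complex(math.cos(math.radians(d)), math.sin(math.radians(d)))
            for ri, d in zip(r, EIGHT))
    assert res.dsi == pytest.approx(abs(z) / r.sum(), abs=1e-12)
    assert res.dsi <= 1.0 + 1e-12
    scaled = direction_selectivity_index(DirectionSeries(EIGHT, c * r))
    assert scaled.dsi == pytest.approx(res.dsi, abs=1e-9)
    assert (scaled.preferred_angle_deg
            == pytest.approx(res.preferred_angle_deg, abs=1e-6))


def test_dsi_all_zero_raises_no_response():
    with pytest.raises(NoResponse):
        direction_selectivity_index(DirectionSeries(EIGHT, np.zeros(8)))


def test_dsi_per_trial_variability():
    d = np.tile(EIGHT, 3)
    r = np.tile([5.0, 2, 1, 0, 0, 0, 1, 2], 3)
    trials = np.repeat([0, 1, 2], 8)
    res = direction_selectivity_index(DirectionSeries(d, r, trials))
    assert res.sd_dsi == pytest.approx(0.0, abs=1e-12)   # identical trials
    assert res.sd_angle_deg == pytest.approx(0.0, abs=1e-9)
    assert len(res.per_trial_dsi) == 3


def test_dsi_rejects_negative_responses():
    with pytest.raises(ValueError):
        DirectionSeries(EIGHT, np.array([1.0, -1, 1, 1, 1, 1, 1, 1]))


def test_circular_sd_wraps():
    assert circular_sd_deg([359.0, 1.0]) == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------- onset

def _biexp(t, t0, rise, decay):
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = 1.0 / (math.exp(-tp / decay) - math.exp(-tp / rise))
    out = norm * (np.exp(-(t - t0) / decay) - np.exp(-(t - t0) / rise))
    out[t < t0] = 0.0
    return out


def test_onset_of_linear_ramp_is_exact():
    dt = 0.1
    t = np.arange(0, 400, dt)
    y = np.where(t >= 100.0, (t - 100.0) * 2.0, 0.0)
    fit = onset_latency(y, dt_ms=dt, baseline_window_ms=50.0)
    assert fit.onset_ms == pytest.approx(100.0, abs=dt)


@pytest.mark.parametrize("t0", [150.0, 200.0, 333.3])
def test_onset_of_biexp_within_one_ms(t0):
    dt = 0.1
    t = np.arange(0, 800, dt)
    y = 100.0 * _biexp(t, t0, 1.0, 10.0)
    fit = onset_latency(y, dt_ms=dt, baseline_window_ms=100.0)
    assert t0 - 0.2 <= fit.onset_ms <= t0 + 1.0
    assert fit.t20_ms < fit.t80_ms


def test_onset_translation_equivariance():
    dt = 0.1
    t = np.arange(0, 800, dt)
    y = 80.0 * _biexp(t, 200.0, 1.0, 10.0)
    shift = 55.0
    y2 = 80.0 * _biexp(t, 200.0 + shift, 1.0, 10.0)
    f1 = onset_latency(y, dt_ms=dt, baseline_window_ms=100.0)
    f2 = onset_latency(y2, dt_ms=dt, baseline_window_ms=100.0)
    assert f2.onset_ms - f1.onset_ms == pytest.approx(shift, abs=0.1)


def test_onset_recovery_under_noise():
    """Mean onset error < 5 ms with noise SD at 10% of peak (100 draws)."""
    dt = 0.1
    t = np.arange(0, 800, dt)
    clean = 100.0 * _biexp(t, 300.0, 1.0, 10.0)
    rng = np.random.default_rng(7)
    errors = []
    for _ in range(100):
        y = clean + rng.normal(0, 10.0, t.size)
        fit = onset_latency(y, dt_ms=dt, baseline_window_ms=200.0,
                            smooth_ms=1.0)
        errors.append(abs(fit.onset_ms - 300.0))
    assert np.mean(errors) < 5.0


def test_onset_flat_trace_raises():
    with pytest.raises(NoResponse):
        onset_latency(np.zeros(5000), dt_ms=0.1)
    with pytest.raises(NoResponse):
        onset_latency(np.random.default_rng(0).normal(0, 1.0, 5000),
                      dt_ms=0.1, baseline_window_ms=200.0)


def test_onset_negative_polarity():
    dt = 0.1
    t = np.arange(0, 800, dt)
    y = -120.0 * _biexp(t, 250.0, 1.0, 10.0)
    fit = onset_latency(y, dt_ms=dt, baseline_window_ms=100.0)
    assert 249.5 <= fit.onset_ms <= 251.0


# ---------------------------------------------------------------- E/I offset

def _pair(te, ti, dt=0.1, amp_e=-150.0, amp_i=200.0):
    t = np.arange(0, 800, dt)
    e = amp_e * _biexp(t, te, 1.0, 10.0)
    i = amp_i * _biexp(t, ti, 0.5, 12.0)
    return e, i


def test_ei_offset_positive_when_excitation_leads():
    e, i = _pair(100.0, 150.0)
    est = ei_temporal_offset(e, i, dt_ms=0.1, baseline_window_ms=50.0)
    assert est.offset_ms == pytest.approx(50.0, abs=1.5)
    assert est.clamped_offset_ms == est.offset_ms


def test_ei_offset_negative_clamps_to_zero():
    e, i = _pair(100.0, 90.0)
    est = ei_temporal_offset(e, i, dt_ms=0.1, baseline_window_ms=50.0)
    assert est.offset_ms == pytest.approx(-10.0, abs=1.5)
    assert est.clamped_offset_ms == 0.0


def test_ei_offset_identical_traces_is_zero():
    t = np.arange(0, 800, 0.1)
    x = 100.0 * _biexp(t, 222.0, 1.0, 10.0)
    est = ei_temporal_offset(x, x, dt_ms=0.1, baseline_window_ms=100.0)
    assert est.offset_ms == 0.0


# ---------------------------------------------------------------- conversion

def test_temporal_to_spatial_offset():
    assert temporal_to_spatial_offset(50.0, 1000.0) == pytest.approx(50.0)
    assert temporal_to_spatial_offset(0.0, 123.0) == 0.0
    with pytest.raises(ValueError):
        temporal_to_spatial_offset(10.0, 0.0)


def test_offset_round_trip_with_schedule_division():
    v = 1234.5
    offset_um = 37.25
    t_ms = offset_um / v * 1000.0
    assert temporal_to_spatial_offset(t_ms, v) == pytest.approx(
        offset_um, abs=1e-9)


# ---------------------------------------------------------------- phases

def _make_trains(early_tuned=True, late_tuned=False, trials=3):
    """Deterministic trains: early burst before 200 ms, sustained after."""
    rng = np.random.default_rng(0)
    out = {}
    for d in EIGHT:
        w_early = max(0.0, math.cos(math.radians(d))) if early_tuned else 1.0
        w_late = max(0.0, math.cos(math.radians(d))) if late_tuned else 1.0
        per_trial = []
        for _ in range(trials):
            early = np.sort(rng.uniform(150, 200, int(round(6 * w_early))))
            late = np.sort(rng.uniform(200, 500, int(round(20 * w_late))))
            per_trial.append(np.concatenate([early, late]))
        out[float(d)] = per_trial
    return out


def test_early_window_sharper_when_only_early_is_tuned():
    spikes = _make_trains(early_tuned=True, late_tuned=False)
    early, peak = phase_tuning(spikes, glut_rf_entry_ms=200.0)
    assert early is not None and peak is not None
    assert early.dsi > peak.dsi


def test_phase_tuning_identical_trials_zero_sd():
    trains = {float(d): [np.array([180.0, 190.0, 250.0, 260.0])] * 3
              if d in (0.0, 45.0) else [np.array([250.0])] * 3
              for d in EIGHT}
    early, peak = phase_tuning(trains, glut_rf_entry_ms=200.0)
    assert early.sd_dsi == pytest.approx(0.0, abs=1e-12)
    assert early.sd_angle_deg == pytest.approx(0.0, abs=1e-9)


def test_phase_tuning_empty_window_returns_none():
    trains = {float(d): [np.array([500.0, 510.0])] for d in EIGHT}
    early, peak = phase_tuning(trains, glut_rf_entry_ms=200.0)
    assert early is None          # nothing before 200 ms
    assert peak is not None
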
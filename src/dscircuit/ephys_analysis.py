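"""Direction-tuning and synaptic-timing statistics for DSGC recordings.

The quantities implemented here are the standard readouts of retinal
direction-selectivity experiments:

* Gaussian-kernel firing-rate estimate (σ = 25 ms by default).
* Direction selectivity index (DSI): the magnitude of the response-weighted
  vector sum over stimulus directions, normalized by the summed responses —
  0 for a perfectly symmetric response, 1 for a response confined to a
  single direction.  The preferred angle is the direction of the resultant.
* Synaptic-current onset latency: a straight line is fit (least squares) to
  the 20-80% rise of the EPSC/IPSC and extrapolated back to the baseline;
  the crossing time is the onset.
* E/I temporal offset: inhibitory-minus-excitatory onset; positive offsets
  mean excitation leads inhibition.  For DSI computations on offsets,
  negative values are clamped to zero.
* Phase-resolved tuning: early-window (before the stimulus enters the
  glutamatergic receptive field) versus peak-window spike counts, with
  across-trial variability of DSI and preferred angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "DirectionSeries",
    "TuningResult",
    "OffsetEstimate",
    "NoResponse",
    "smooth_firing_rate",
    "direction_selectivity_index",
    "onset_latency",
    "ei_temporal_offset",
    "temporal_to_spatial_offset",
    "phase_tuning",
    "circular_mean_deg",
    "circular_sd_deg",
]


class NoResponse(Exception):
    """Raised when a response is absent (all-zero series, no qualifying peak)."""


# --------------------------------------------------------------------------
# firing rate
# --------------------------------------------------------------------------

def smooth_firing_rate(
    spike_times_ms: Sequence[float] | np.ndarray,
    sigma_ms: float = 25.0,
    dt_ms: float = 1.0,
    t_start_ms: float | None = None,
    t_stop_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate (Hz) by Gaussian-kernel convolution.

    The kernel has unit area (in seconds), so the integral of the returned
    trace equals the spike count.  Returns ``(time_ms, rate_hz)``.  The
    default window pads 5σ beyond the first/last spike so no kernel mass is
    lost; an empty spike list gives an all-zero trace.
    """
    if sigma_ms <= 0:
        raise ValueError("kernel sigma must be positive")
    st = np.sort(np.asarray(spike_times_ms, dtype=float))
    pad = 5.0 * sigma_ms
    if t_start_ms is None:
        t_start_ms = (st[0] - pad) if st.size else 0.0
    if t_stop_ms is None:
        t_stop_ms = (st[-1] + pad) if st.size else 100.0
    t = np.arange(t_start_ms, t_stop_ms + dt_ms / 2, dt_ms)
    rate = np.zeros_like(t)
    if st.size:
        norm = 1.0 / (sigma_ms / 1000.0 * math.sqrt(2.0 * math.pi))
        for s in st:   # exact evaluation; spike counts are small
            rate += norm * np.exp(-0.5 * ((t - s) / sigma_ms) ** 2)
    return t, rate


# --------------------------------------------------------------------------
# DSI
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionSeries:
    """Per-direction (optionally per-trial) non-negative response metrics."""

    directions_deg: np.ndarray
    responses: np.ndarray
    trial_ids: np.ndarray | None = None
    metric_kind: str = "spike_count"

    def __post_init__(self):
        d = np.asarray(self.directions_deg, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape:
            raise ValueError("directions and responses must align")
        if np.unique(np.mod(d, 360.0)).size < 2:
            raise ValueError("need at least two distinct directions")
        if np.any(r < 0):
            raise ValueError("responses must be non-negative "
                             "(clamp E/I offsets upstream)")
        object.__setattr__(self, "directions_deg", d)
        object.__setattr__(self, "responses", r)
        if self.trial_ids is not None:
            ti = np.asarray(self.trial_ids)
            if ti.shape != d.shape:
                raise ValueError("trial_ids must align with directions")
            object.__setattr__(self, "trial_ids", ti)


@dataclass(frozen=True)
class TuningResult:
    dsi: float
    preferred_angle_deg: float
    per_trial_dsi: tuple[float, ...] = ()
    per_trial_angle_deg: tuple[float, ...] = ()
    sd_dsi: float | None = None
    sd_angle_deg: float | None = None
    metric_kind: str = "spike_count"

    def __post_init__(self):
        if not (0.0 <= self.dsi <= 1.0 + 1e-12):
            raise ValueError("DSI must lie in [0, 1]")


def _vector_sum(directions_deg: np.ndarray, responses: np.ndarray
                ) -> tuple[float, float]:
    total = responses.sum()
    if total <= 0:
        raise NoResponse("all responses are zero; DSI is undefined")
    z = np.sum(responses * np.exp(1j * np.deg2rad(directions_deg)))
    return float(abs(z) / total), float(np.rad2deg(np.angle(z)) % 360.0)


def circular_mean_deg(angles_deg: Sequence[float]) -> float:
    z = np.mean(np.exp(1j * np.deg2rad(np.asarray(angles_deg, dtype=float))))
    return float(np.rad2deg(np.angle(z)) % 360.0)


def circular_sd_deg(angles_deg: Sequence[float]) -> float:
    """SD of angles as deviations from the circular mean, wrapped to ±180°."""
    mu = circular_mean_deg(angles_deg)
    dev = (np.asarray(angles_deg, dtype=float) - mu + 180.0) % 360.0 - 180.0
    return float(np.sqrt(np.mean(dev ** 2)))


def direction_selectivity_index(series: DirectionSeries) -> TuningResult:
    """Normalized vector-sum DSI and preferred angle.

    With trial ids present, the headline DSI/angle are computed on the
    trial-summed responses and per-trial values plus across-trial SDs are
    reported as the variability summary (SDs need ≥ 2 trials).
    """
    dsi, angle = _vector_sum(series.directions_deg, series.responses)
    per_dsi: list[float] = []
    per_angle: list[float] = []
    sd_dsi = sd_angle = None
    if series.trial_ids is not None:
        for t in np.unique(series.trial_ids):
            mask = series.trial_ids == t
            try:
                d_t, a_t = _vector_sum(series.directions_deg[mask],
                                       series.responses[mask])
            except NoResponse:
                continue
            per_dsi.append(d_t)
            per_angle.append(a_t)
        if len(per_dsi) >= 2:
            sd_dsi = float(np.std(per_dsi, ddof=1))
            sd_angle = circular_sd_deg(per_angle)
    return TuningResult(dsi=dsi, preferred_angle_deg=angle,
                        per_trial_dsi=tuple(per_dsi),
                        per_trial_angle_deg=tuple(per_angle),
                        sd_dsi=sd_dsi, sd_angle_deg=sd_angle,
                        metric_kind=series.metric_kind)


# --------------------------------------------------------------------------
# onset latency / E-I offset
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetFit:
    onset_ms: float
    t20_ms: float
    t80_ms: float
    slope_per_ms: float
    peak_time_ms: float
    peak_amplitude: float
    baseline: float


@dataclass(frozen=True)
class OffsetEstimate:
    excitation_onset_ms: float
    inhibition_onset_ms: float
    offset_ms: float
    clamped_offset_ms: float
    excitation_fit: OnsetFit | None = None
    inhibition_fit: OnsetFit | None = None


def onset_latency(
    trace: Recording | np.ndarray,
    polarity: str = "auto",
    baseline_window_ms: float = 200.0,
    noise_factor: float = 5.0,
    min_peak_frac: float = 0.2,
    anchor: str = "first_peak",
    smooth_ms: float = 0.0,
    t_max_ms: float | None = None,
    dt_ms: float | None = None,
    t0_ms: float = 0.0,
) -> OnsetFit:
    """Response onset by back-extrapolation of the 20-80% rise.

    Baseline level and SD come from the pre-stimulus window.  The response
    peak is the first local maximum (after polarity normalization) exceeding
    baseline by ``noise_factor`` baseline SDs; the 20% and 80% crossings are
    located scanning back from that peak (first-crossing rule on the final
    approach), a least-squares line through all samples in between is
    extrapolated to the baseline level, and its crossing time is the onset.

    Raises :class:`NoResponse` when no peak qualifies.
    """
    if isinstance(trace, Recording):
        y = trace.values.astype(float)
        dt_ms = trace.dt_ms
        t0_ms = trace.t0_ms
    else:
        y = np.asarray(trace, dtype=float)
        if dt_ms is None:
            raise ValueError("dt_ms required for bare arrays")
    if t_max_ms is not None:
        # confine the analysis to the initial response (e.g. the entry of a
        # moving stimulus into the receptive field); later growth of a
        # slowly accumulating current must not redefine the rise amplitude
        y = y[: max(2, int(round((t_max_ms - t0_ms) / dt_ms)))]
    nbase = max(2, int(round(baseline_window_ms / dt_ms)))
    nbase = min(nbase, y.size)
    baseline = float(np.mean(y[:nbase]))
    base_sd = float(np.std(y[:nbase]))

    if polarity == "auto":
        excursion = y - baseline
        sign = 1.0 if abs(excursion.max()) >= abs(excursion.min()) else -1.0
    elif polarity in ("positive", "outward"):
        sign = 1.0
    elif polarity in ("negative", "inward"):
        sign = -1.0
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    s = sign * (y - baseline)
    if smooth_ms > 0:
        # symmetric pre-fit smoothing: suppresses release-noise bumps in
        # ensemble currents without shifting the rise (zero-phase kernel)
        from scipy.ndimage import gaussian_filter1d
        s = gaussian_filter1d(s, smooth_ms / dt_ms, mode="nearest")

    threshold = max(noise_factor * base_sd, min_peak_frac * s.max(), 1e-12)
    if anchor == "rise":
        # amplitude referenced to the absolute maximum; the 20%/80% levels
        # are located by FIRST upward crossing (robust for ensemble currents
        # that ramp into a fluctuating plateau with no clear first peak)
        if s.max() <= max(noise_factor * base_sd, 1e-12):
            raise NoResponse("no peak exceeds baseline noise")
        amp = s.max()
        i20f = int(np.argmax(s >= 0.2 * amp))
        i80f = int(np.argmax(s >= 0.8 * amp))
        i80f = max(i80f, i20f + 1)
        idx = np.arange(i20f, min(i80f + 1, y.size))
        tt = t0_ms + idx * dt_ms
        slope, intercept = np.polyfit(tt, s[idx], 1)
        if slope <= 0:
            raise NoResponse("non-rising 20-80% segment")
        onset = float(-intercept / slope)
        return OnsetFit(onset_ms=onset, t20_ms=t0_ms + i20f * dt_ms,
                        t80_ms=t0_ms + i80f * dt_ms,
                        slope_per_ms=float(slope),
                        peak_time_ms=t0_ms + int(np.argmax(s)) * dt_ms,
                        peak_amplitude=float(amp), baseline=baseline)
    if anchor == "global":
        # anchor the rise on the absolute maximum: translation-consistent for
        # slowly ramping ensemble currents whose first local maxima are
        # release-noise bumps
        if s.max() <= max(noise_factor * base_sd, 1e-12):
            raise NoResponse("no peak exceeds baseline noise")
        ipk = int(np.argmax(s))
    elif anchor == "first_peak":
        # prominence only rejects sub-threshold ripple: plateau fluctuations
        # after the rise must not displace the anchor from the first shoulder
        peaks, _ = signal.find_peaks(s, height=threshold,
                                     prominence=threshold / 4.0)
        if peaks.size:
            ipk = int(peaks[0])
        elif s.max() > threshold:
            ipk = int(np.argmax(s))   # monotone rise without a turning point
        else:
            raise NoResponse("no peak exceeds baseline noise")
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    amp = s[ipk]

    def back_crossing(level: float) -> float:
        i = ipk
        while i > 0 and s[i] > level:
            i -= 1
        if i == ipk:
            return t0_ms + ipk * dt_ms
        # linear interpolation between the last sub-level and first supra-level sample
        frac = (level - s[i]) / (s[i + 1] - s[i]) if s[i + 1] != s[i] else 0.0
        return t0_ms + (i + frac) * dt_ms

    t20 = back_crossing(0.2 * amp)
    t80 = back_crossing(0.8 * amp)
    i20 = int(math.floor((t20 - t0_ms) / dt_ms))
    i80 = int(math.ceil((t80 - t0_ms) / dt_ms))
    i80 = max(i80, i20 + 1)
    idx = np.arange(i20, min(i80 + 1, y.size))
    tt = t0_ms + idx * dt_ms
    slope, intercept = np.polyfit(tt, s[idx], 1)
    if slope <= 0:
        raise NoResponse("non-rising 20-80% segment")
    onset = float(-intercept / slope)   # where the fit line meets baseline (s=0)
    return OnsetFit(onset_ms=onset, t20_ms=float(t20), t80_ms=float(t80),
                    slope_per_ms=float(slope), peak_time_ms=t0_ms + ipk * dt_ms,
                    peak_amplitude=float(amp), baseline=baseline)


def ei_temporal_offset(
    epsc: Recording | np.ndarray,
    ipsc: Recording | np.ndarray,
    dt_ms: float | None = None,
    **onset_kwargs,
) -> OffsetEstimate:
    """Inhibition-minus-excitation onset latency.

    Positive offsets mean excitation leads inhibition; the clamped variant
    (negatives set to zero) is the one used for offset-based DSI.
    """
    efit = onset_latency(epsc, dt_ms=dt_ms, **onset_kwargs)
    ifit = onset_latency(ipsc, dt_ms=dt_ms, **onset_kwargs)
    off = ifit.onset_ms - efit.onset_ms
    return OffsetEstimate(
        excitation_onset_ms=efit.onset_ms, inhibition_onset_ms=ifit.onset_ms,
        offset_ms=off, clamped_offset_ms=max(off, 0.0),
        excitation_fit=efit, inhibition_fit=ifit)


def temporal_to_spatial_offset(offset_ms: float, velocity_um_s: float) -> float:
    """Spatial offset (µm) = velocity × temporal offset."""
    if velocity_um_s <= 0:
        raise ValueError("velocity must be positive")
    return offset_ms / 1000.0 * velocity_um_s


# --------------------------------------------------------------------------
# phase-resolved tuning
# --------------------------------------------------------------------------

def phase_tuning(
    spikes_by_direction: Mapping[float, Sequence[Sequence[float] | np.ndarray]],
    glut_rf_entry_ms: float,
    early_span_ms: float = 50.0,
    peak_span_ms: float = 50.0,
    rate_sigma_ms: float = 25.0,
) -> tuple[TuningResult | None, TuningResult | None]:
    """Early-phase vs peak-phase direction tuning.

    ``spikes_by_direction`` maps direction (deg) to a list of per-trial spike
    time arrays, all aligned to a common clock in which the stimulus enters
    the glutamatergic receptive field at ``glut_rf_entry_ms``.  The early
    window is the ``early_span_ms`` preceding that entry (spikes there are
    driven by the spatially advanced cholinergic input); the peak window is
    ``peak_span_ms`` centred on the peak of the trial-averaged smoothed rate
    in the preferred direction.  Each window yields a spike-count DSI with
    per-trial variability; a window with no spikes in any direction returns
    ``None``.
    """
    directions = sorted(spikes_by_direction)
    n_trials = {d: len(spikes_by_direction[d]) for d in directions}

    def window_result(lo: float, hi: float) -> TuningResult | None:
        dirs, counts, trials = [], [], []
        for d in directions:
            for ti, st in enumerate(spikes_by_direction[d]):
                st = np.asarray(st, dtype=float)
                dirs.append(d)
                counts.append(int(np.sum((st >= lo) & (st < hi))))
                trials.append(ti)
        if sum(counts) < 1:
            return None
        series = DirectionSeries(np.array(dirs, dtype=float),
                                 np.array(counts, dtype=float),
                                 np.array(trials))
        return direction_selectivity_index(series)

    early = window_result(glut_rf_entry_ms - early_span_ms, glut_rf_entry_ms)

    # preferred direction from total counts, then locate the rate peak there
    total = {d: sum(len(np.asarray(st)) for st in spikes_by_direction[d])
             for d in directions}
    if sum(total.values()) < 1:
        return early, None
    series_all = DirectionSeries(
        np.array(directions, dtype=float),
        np.array([total[d] for d in directions], dtype=float))
    headline = direction_selectivity_index(series_all)
    pref = min(directions,
               key=lambda d: abs((d - headline.preferred_angle_deg + 180.0)
                                 % 360.0 - 180.0))
    all_pref = np.concatenate([np.asarray(st, dtype=float)
                               for st in spikes_by_direction[pref]]) \
        if total[pref] else np.array([])
    if all_pref.size == 0:
        return early, None
    t, rate = smooth_firing_rate(all_pref, sigma_ms=rate_sigma_ms)
    t_peak = float(t[np.argmax(rate)])
    peak = window_result(t_peak - peak_span_ms / 2.0,
                         t_peak + peak_span_ms / 2.0)
    return early, peak
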
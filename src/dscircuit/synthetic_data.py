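"""Surrogate DSGC recordings with known ground truth.

Generates direction-tuned EPSC/IPSC pairs and spike trains that emulate the
measurement structure of moving-bar experiments — excitation isotropically
advanced by a fixed spatial offset (the cholinergic receptive-field
displacement), inhibition with direction-tuned onset offsets and amplitudes —
so every estimator and the full analysis pipeline can be validated against
configured truth without running the compartmental simulator.

The generator's direction-tuning rule uses the same sigmoid shape as the
release-probability equation, renormalized so the preferred/null endpoint
values are met exactly at 0° and 180° (the raw sigmoid leaves a 2% span
residual at the endpoints; the generator promises exact ground truth).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circuit_geometry import angle_distance
from .recording import Recording

__all__ = ["SyntheticGroundTruth", "synth_current_pair", "synth_spike_trains",
           "write_fixture"]


def _unit_sigmoid(angle_dist_deg: float, midpoint: float = 74.69,
                  slope: float = 24.36, span: float = 0.98) -> float:
    """0 at angle 0, exactly 1 at angle 180, sigmoidal in between."""
    def s(a: float) -> float:
        return 1.0 - span / (1.0 + math.exp((a - midpoint) / slope))
    lo, hi = s(0.0), s(180.0)
    return (s(angle_dist_deg) - lo) / (hi - lo)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Configured truth for one synthetic cell.

    Onsets are tied to the bar geometry: the stimulus reaches the (offset-
    free) glutamatergic receptive field at ``rf_entry_ms``; excitation leads
    it by ``exc_offset_um / velocity`` in every direction, inhibition by its
    direction-tuned offset (``inh_pOff_um`` preferred → ``inh_nOff_um``
    null).  Inhibition amplitude runs from ``inh_amp_pref_frac`` × the null
    amplitude (preferred) to the full null amplitude.
    """

    preferred_angle_deg: float = 0.0
    velocity_um_s: float = 1000.0
    rf_entry_ms: float = 200.0
    exc_offset_um: float = 50.0
    inh_pOff_um: float = 0.0
    inh_nOff_um: float = 50.0
    exc_amp_pa: float = 200.0
    inh_amp_null_pa: float = 300.0
    inh_amp_pref_frac: float = 0.05
    exc_rise_ms: float = 1.0
    exc_decay_ms: float = 25.0
    inh_rise_ms: float = 0.5
    inh_decay_ms: float = 60.0
    sustain_ms: float = 300.0
    noise_sd_pa: float = 0.0
    amplitude_tuning: bool = True
    temporal_offsets: bool = True
    # spike-rate model constants (documented, arbitrary): drive->rate gain
    # and the relative weights of the early (cholinergic) and sustained
    # (glutamatergic) excitatory drive and of inhibition
    rate_gain_hz: float = 100.0
    exc_drive: float = 1.0
    glut_drive: float = 1.0
    inh_drive_null: float = 1.5

    def __post_init__(self):
        if self.noise_sd_pa < 0:
            raise ValueError("noise SD must be >= 0")
        if self.velocity_um_s <= 0:
            raise ValueError("velocity must be positive")

    # -- per-direction truth ----------------------------------------------

    def exc_onset_ms(self, direction_deg: float) -> float:
        off = self.exc_offset_um if self.temporal_offsets else 0.0
        return self.rf_entry_ms - off / self.velocity_um_s * 1000.0

    def inh_offset_um(self, direction_deg: float) -> float:
        if not self.temporal_offsets:
            return 0.0
        w = _unit_sigmoid(angle_distance(direction_deg,
                                         self.preferred_angle_deg))
        return self.inh_pOff_um + (self.inh_nOff_um - self.inh_pOff_um) * w

    def inh_onset_ms(self, direction_deg: float) -> float:
        return (self.rf_entry_ms
                - self.inh_offset_um(direction_deg)
                / self.velocity_um_s * 1000.0)

    def inh_amplitude_pa(self, direction_deg: float) -> float:
        if not self.amplitude_tuning:
            return self.inh_amp_null_pa
        w = _unit_sigmoid(angle_distance(direction_deg,
                                         self.preferred_angle_deg))
        frac = self.inh_amp_pref_frac + (1.0 - self.inh_amp_pref_frac) * w
        return self.inh_amp_null_pa * frac

    def ei_offset_ms(self, direction_deg: float) -> float:
        """Ground-truth inhibition-minus-excitation onset difference."""
        return self.inh_onset_ms(direction_deg) - self.exc_onset_ms(direction_deg)

    # -- spike-rate profile -----------------------------------------------

    def rate_segments(self, direction_deg: float
                      ) -> list[tuple[float, float, float]]:
        """Piecewise-constant firing rate as (t0_ms, t1_ms, rate_hz).

        The drive is rectified excitation-minus-inhibition: cholinergic
        excitation turns on at its advanced onset, glutamatergic drive adds
        from receptive-field entry, inhibition subtracts from its own onset
        with the direction-tuned amplitude.  Early-window rate therefore
        depends only on the offset mechanism; sustained rate only on the
        amplitude mechanism.
        """
        t_e = self.exc_onset_ms(direction_deg)
        t_i = self.inh_onset_ms(direction_deg)
        t_g = self.rf_entry_ms
        t_end = self.rf_entry_ms + self.sustain_ms
        inh = (self.inh_drive_null
               * self.inh_amplitude_pa(direction_deg) / self.inh_amp_null_pa)
        edges = sorted({t_e, t_i, t_g, t_end})
        segs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= t_e or lo >= t_end:
                continue
            drive = 0.0
            if lo >= t_e:
                drive += self.exc_drive
            if lo >= t_g:
                drive += self.glut_drive
            if lo >= t_i:
                drive -= inh
            rate = self.rate_gain_hz * max(drive, 0.0)
            if rate > 0:
                segs.append((lo, hi, rate))
        return segs

    def expected_count(self, direction_deg: float,
                       window: tuple[float, float] | None = None) -> float:
        """Analytic mean spike count (optionally within a time window)."""
        total = 0.0
        for lo, hi, rate in self.rate_segments(direction_deg):
            if window is not None:
                lo, hi = max(lo, window[0]), min(hi, window[1])
            if hi > lo:
                total += rate * (hi - lo) / 1000.0
        return total

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in self.__dataclass_fields__},
                          indent=1)


def _biexp(t_ms: np.ndarray, onset_ms: float, rise: float, decay: float
           ) -> np.ndarray:
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = 1.0 / (math.exp(-tp / decay) - math.exp(-tp / rise))
    dt = np.clip(t_ms - onset_ms, 0.0, None)
    w = norm * (np.exp(-dt / decay) - np.exp(-dt / rise))
    w[t_ms < onset_ms] = 0.0
    return w


def synth_current_pair(
    truth: SyntheticGroundTruth, direction_deg: float, seed: int = 0,
    dt_ms: float = 0.1, duration_ms: float | None = None,
) -> tuple[Recording, Recording]:
    """One EPSC/IPSC pair for a single direction.

    EPSC is inward-negative (recorded at the inhibitory reversal), IPSC
    outward-positive (recorded at 0 mV); both are bi-exponentials at the
    ground-truth onsets plus white Gaussian noise.  Metadata carries the
    truth for test harnesses.
    """
    if duration_ms is None:
        duration_ms = truth.rf_entry_ms + truth.sustain_ms + 200.0
    t = np.arange(0.0, duration_ms, dt_ms)
    rng = np.random.default_rng(seed)
    epsc = -truth.exc_amp_pa * _biexp(t, truth.exc_onset_ms(direction_deg),
                                      truth.exc_rise_ms, truth.exc_decay_ms)
    ipsc = truth.inh_amplitude_pa(direction_deg) * _biexp(
        t, truth.inh_onset_ms(direction_deg),
        truth.inh_rise_ms, truth.inh_decay_ms)
    if truth.noise_sd_pa > 0:
        epsc = epsc + rng.normal(0.0, truth.noise_sd_pa, t.size)
        ipsc = ipsc + rng.normal(0.0, truth.noise_sd_pa, t.size)
    meta = {"direction_deg": direction_deg, "seed": seed, "synthetic": True,
            "truth_exc_onset_ms": truth.exc_onset_ms(direction_deg),
            "truth_inh_onset_ms": truth.inh_onset_ms(direction_deg),
            "velocity_um_s": truth.velocity_um_s}
    return (
        Recording(mode="voltage_clamp_current", dt_ms=dt_ms, values=epsc,
                  hold_potential_mv=-60.0, metadata=dict(meta, current="EPSC")),
        Recording(mode="voltage_clamp_current", dt_ms=dt_ms, values=ipsc,
                  hold_potential_mv=0.0, metadata=dict(meta, current="IPSC")),
    )


def synth_spike_trains(
    truth: SyntheticGroundTruth,
    directions_deg: list[float],
    trials: int,
    seed: int = 0,
) -> dict[float, list[Recording]]:
    """Inhomogeneous-Poisson spike trains per direction and trial."""
    if trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    out: dict[float, list[Recording]] = {}
    for d in directions_deg:
        segs = truth.rate_segments(d)
        recs = []
        for trial in range(trials):
            times: list[np.ndarray] = []
            for lo, hi, rate in segs:
                n = rng.poisson(rate * (hi - lo) / 1000.0)
                if n:
                    times.append(rng.uniform(lo, hi, n))
            st = np.sort(np.concatenate(times)) if times else np.array([])
            # enforce strictly increasing times (Poisson ties are measure-zero
            # but float duplicates can occur)
            if st.size > 1:
                st = st[np.concatenate(([True], np.diff(st) > 0))]
            recs.append(Recording(
                mode="spike_times", spike_times_ms=st,
                metadata={"direction_deg": d, "trial": trial, "seed": seed,
                          "synthetic": True,
                          "rf_entry_ms": truth.rf_entry_ms}))
        out[d] = recs
    return out


def write_fixture(
    out_dir: str | Path,
    truth: SyntheticGroundTruth,
    directions_deg: list[float] | None = None,
    trials: int = 5,
    seed: int = 0,
) -> Path:
    """Emit a ready-made fixture directory (currents + spikes + manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    directions = directions_deg or [45.0 * k for k in range(8)]
    manifest: dict = {"seed": seed, "trials": trials, "directions": directions,
                      "truth": json.loads(truth.to_json()), "files": []}
    for i, d in enumerate(directions):
        epsc, ipsc = synth_current_pair(truth, d, seed=seed + i)
        for rec, tag in ((epsc, "epsc"), (ipsc, "ipsc")):
            name = f"{tag}_dir{int(round(d)):03d}.csv"
            rec.save(out_dir / name)
            manifest["files"].append(name)
    spikes = synth_spike_trains(truth, directions, trials, seed=seed)
    for d, recs in spikes.items():
        for ti, rec in enumerate(recs):
            name = f"spikes_dir{int(round(d)):03d}_trial{ti:02d}.csv"
            rec.save(out_dir / name)
            manifest["files"].append(name)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
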
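"""In-silico experiment protocols: mechanism dissection and velocity sweep.

Three model configurations dissect the two direction-selectivity mechanisms:

* ``both`` — direction-tuned GABA release probability (amplitude asymmetry)
  and direction-tuned spatial offsets (timing asymmetry), the control model.
* ``offsets_only`` — GABA release probability held at its null value in all
  directions (the non-directional starburst configuration); tuning arises
  purely from E/I timing offsets.
* ``amplitude_only`` — all spatial offsets removed (co-extensive receptive
  fields); tuning arises purely from the GABA amplitude asymmetry.

The velocity sweep runs the offsets-only configuration (summed E:I peak
conductance fixed at 1:2) across a velocity grid and reports spike counts,
DSI and preferred angle per velocity; the added lowest velocity exposes
null-direction leak-through when inhibition ends long before excitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biophysics import BiophysicsConfig, Cell, build_cell
from .circuit_geometry import (
    ArborConfig,
    BarStimulus,
    DirectionalTuning,
    ReceptorSpec,
    SynapseSite,
    activation_schedule,
    default_transmitter_tuning,
    generate_arbor,
    place_synapses,
)
from .ephys_analysis import (
    DirectionSeries,
    NoResponse,
    TuningResult,
    direction_selectivity_index,
    phase_tuning,
)
from .recording import Recording

__all__ = [
    "ExperimentConfig",
    "default_model",
    "apply_ei_ratio",
    "glut_rf_entry_ms",
    "simulate_bar_response",
    "run_direction_sweep",
    "measure_ei_offset",
    "experiment_mechanism_dissection",
    "experiment_velocity_sweep",
]

MECHANISM_SETTINGS = ("both", "offsets_only", "amplitude_only")


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared protocol parameters.

    Mechanism toggles map to tuning configurations: ``amplitude_tuning``
    off clamps GABA release probability at the null value; ``temporal_offsets``
    off zeroes every spatial offset; ``cholinergic_synapses`` off removes
    the nicotinic conductance entirely.
    """

    directions_deg: tuple[float, ...] = tuple(45.0 * k for k in range(8))
    velocities_um_s: tuple[float, ...] = (150.0, 300.0, 600.0, 1200.0, 2400.0)
    standard_velocity_um_s: float = 1000.0
    trials: int = 20
    seed: int = 0
    noise: bool = True
    amplitude_tuning: bool = True
    temporal_offsets: bool = True
    cholinergic_synapses: bool = True
    early_span_ms: float = 50.0
    peak_span_ms: float = 50.0
    out_dir: str | None = None

    def __post_init__(self):
        if len(self.directions_deg) < 1 or len(self.velocities_um_s) < 1:
            raise ValueError("need at least one direction and velocity")
        if self.trials < 1:
            raise ValueError("need at least one trial")


def default_model(
    arbor_seed: int = 1,
    arbor_config: ArborConfig = ArborConfig(),
    synapse_spacing_um: float = 10.0,
    receptors: dict[str, ReceptorSpec] | None = None,
    biophysics: BiophysicsConfig = BiophysicsConfig(),
) -> tuple[Cell, list[SynapseSite]]:
    """The standard model cell used by all experiment protocols."""
    morph = generate_arbor(arbor_config, seed=arbor_seed)
    sites = place_synapses(morph, synapse_spacing_um, seed=arbor_seed,
                           receptors=receptors)
    cell = build_cell(morph, sites, biophysics)
    return cell, sites


def apply_ei_ratio(sites: Sequence[SynapseSite], ratio: float = 2.0
                   ) -> list[SynapseSite]:
    """Rescale GABA peak conductances so summed I = ``ratio`` × summed E."""
    exc = sum(s.receptors["glutamate"].gmax_ns
              + s.receptors["acetylcholine"].gmax_ns for s in sites)
    inh = sum(s.receptors["gaba"].gmax_ns for s in sites)
    if inh <= 0:
        raise ValueError("no GABA conductance to rescale")
    scale = ratio * exc / inh
    out = []
    for s in sites:
        g = s.receptors["gaba"]
        new = dict(s.receptors)
        new["gaba"] = ReceptorSpec(g.rise_ms, g.decay_ms,
                                   g.gmax_ns * scale, g.reversal_mv)
        out.append(SynapseSite(s.site_id, s.compartment_id, s.position, new))
    return out


def _setting_tuning(name: str, config: ExperimentConfig
                    ) -> dict[str, DirectionalTuning]:
    if name == "both":
        return default_transmitter_tuning(
            temporal_offsets=config.temporal_offsets)
    if name == "offsets_only":
        return default_transmitter_tuning(non_ds_gaba=True)
    if name == "amplitude_only":
        return default_transmitter_tuning(temporal_offsets=False)
    raise ValueError(f"unknown mechanism setting {name!r}")


def _strip_cholinergic(sites: Sequence[SynapseSite]) -> list[SynapseSite]:
    out = []
    for s in sites:
        a = s.receptors["acetylcholine"]
        new = dict(s.receptors)
        new["acetylcholine"] = ReceptorSpec(a.rise_ms, a.decay_ms, 0.0,
                                            a.reversal_mv)
        out.append(SynapseSite(s.site_id, s.compartment_id, s.position, new))
    return out


def glut_rf_entry_ms(sites: Sequence[SynapseSite], stimulus: BarStimulus
                     ) -> float:
    """When the bar's leading edge reaches the nearest (offset-free)
    glutamatergic synapse — the receptive-field entry used for alignment."""
    theta = np.deg2rad(stimulus.direction_deg)
    proj = np.array([s.position[0] * np.cos(theta)
                     + s.position[1] * np.sin(theta) for s in sites])
    return float((proj.min() - stimulus.start_position_um)
                 / stimulus.velocity_um_s * 1000.0)


def simulate_bar_response(
    cell: Cell,
    sites: Sequence[SynapseSite],
    tuning: dict[str, DirectionalTuning],
    direction_deg: float,
    velocity_um_s: float,
    trial_seed: int,
    noise: bool = True,
    tail_ms: float = 150.0,
) -> Recording:
    """One current-clamp trial for one bar sweep; returns the spike recording
    (aligned metadata carries the glutamate receptive-field entry time)."""
    stim = BarStimulus(direction_deg=direction_deg,
                       velocity_um_s=velocity_um_s)
    schedule = activation_schedule(stim, sites, tuning, seed=trial_seed)
    duration = schedule.last_time_ms + tail_ms
    spikes, _ = cell.run_current_clamp(schedule, duration,
                                       noise_seed=trial_seed + 1,
                                       noise=noise)
    spikes.metadata.update(
        direction_deg=direction_deg, velocity_um_s=velocity_um_s,
        trial_seed=trial_seed,
        rf_entry_ms=glut_rf_entry_ms(sites, stim))
    return spikes


def run_direction_sweep(
    cell: Cell,
    sites: Sequence[SynapseSite],
    tuning: dict[str, DirectionalTuning],
    config: ExperimentConfig,
    velocity_um_s: float | None = None,
    seed_offset: int = 0,
) -> dict[float, list[Recording]]:
    """Spike recordings for every direction × trial at one velocity."""
    v = velocity_um_s or config.standard_velocity_um_s
    out: dict[float, list[Recording]] = {}
    for di, d in enumerate(config.directions_deg):
        recs = []
        for trial in range(config.trials):
            ts = (config.seed + seed_offset + 7919 * trial + 104729 * di) \
                % (2 ** 31)
            recs.append(simulate_bar_response(cell, sites, tuning, d, v, ts,
                                              noise=config.noise))
        out[d] = recs
    return out


def _count_table(sweep: dict[float, list[Recording]]) -> pd.DataFrame:
    rows = [
        {"direction_deg": d, "trial": ti, "spikes": rec.n_spikes,
         "velocity_um_s": rec.metadata.get("velocity_um_s")}
        for d, recs in sweep.items() for ti, rec in enumerate(recs)
    ]
    return pd.DataFrame(rows)


def _tuning_from_table(table: pd.DataFrame) -> TuningResult | None:
    try:
        return direction_selectivity_index(DirectionSeries(
            table["direction_deg"].to_numpy(float),
            table["spikes"].to_numpy(float),
            table["trial"].to_numpy()))
    except NoResponse:
        return None


def _aligned_spike_dict(sweep: dict[float, list[Recording]]
                        ) -> tuple[dict[float, list[np.ndarray]], float]:
    """Shift each direction's trains to a common receptive-field entry."""
    entries = {d: recs[0].metadata["rf_entry_ms"] for d, recs in sweep.items()}
    ref = float(np.mean(list(entries.values())))
    shifted = {
        d: [np.asarray(r.spike_times_ms) - entries[d] + ref for r in recs]
        for d, recs in sweep.items()
    }
    return shifted, ref


def experiment_mechanism_dissection(
    config: ExperimentConfig,
    cell: Cell | None = None,
    sites: Sequence[SynapseSite] | None = None,
) -> dict[str, dict]:
    """Run the three mechanism settings; per setting return the spike-count
    table, whole-response tuning, and early/peak phase tuning."""
    if cell is None or sites is None:
        cell, sites = default_model()
    if not config.cholinergic_synapses:
        sites = _strip_cholinergic(sites)
        cell = build_cell(cell.morphology, sites, cell.config)
    results: dict[str, dict] = {}
    for si, name in enumerate(MECHANISM_SETTINGS):
        tuning = _setting_tuning(name, config)
        sweep = run_direction_sweep(cell, sites, tuning, config,
                                    seed_offset=1_000_003 * si)
        table = _count_table(sweep)
        overall = _tuning_from_table(table)
        if overall is None:
            raise RuntimeError(
                f"calibration failure: no spikes in any direction for "
                f"setting {name!r}")
        shifted, ref = _aligned_spike_dict(sweep)
        early, peak = phase_tuning(shifted, glut_rf_entry_ms=ref,
                                   early_span_ms=config.early_span_ms,
                                   peak_span_ms=config.peak_span_ms)
        early_total = sum(
            int(((st >= ref - config.early_span_ms) & (st < ref)).sum())
            for recs in shifted.values() for st in recs)
        results[name] = {"counts": table, "tuning": overall,
                         "early": early, "peak": peak,
                         "early_total_spikes": early_total,
                         "total_spikes": int(table["spikes"].sum()),
                         "rf_entry_ms": ref}
    if config.out_dir:
        _write_dissection(Path(config.out_dir), results)
    return results


def experiment_velocity_sweep(
    config: ExperimentConfig,
    cell: Cell | None = None,
    sites: Sequence[SynapseSite] | None = None,
    ei_ratio: float = 2.0,
) -> pd.DataFrame:
    """Offsets-only fixed-E/I-ratio sweep across velocities.

    Returns a tidy table (velocity, direction, trial, spikes) with a
    per-velocity summary (DSI, preferred angle, preferred/null mean counts)
    attached as ``DataFrame.attrs['summary']``.
    """
    if cell is None or sites is None:
        cell, sites = default_model()
    sites = apply_ei_ratio(sites, ei_ratio)
    cell = build_cell(cell.morphology, sites, cell.config)
    tuning = _setting_tuning("offsets_only", config)
    tables = []
    summary_rows = []
    for vi, v in enumerate(sorted(config.velocities_um_s)):
        sweep = run_direction_sweep(cell, sites, tuning, config,
                                    velocity_um_s=v,
                                    seed_offset=2_000_003 * vi)
        table = _count_table(sweep)
        tables.append(table)
        tun = _tuning_from_table(table)
        by_dir = table.groupby("direction_deg")["spikes"].mean()
        pref_dir = min(by_dir.index, key=lambda d: abs(
            (d - (tun.preferred_angle_deg if tun else 0.0) + 180) % 360 - 180))
        null_dir = (pref_dir + 180.0) % 360.0
        summary_rows.append({
            "velocity_um_s": v,
            "dsi": tun.dsi if tun else np.nan,
            "preferred_angle_deg": tun.preferred_angle_deg if tun else np.nan,
            "pref_mean_spikes": by_dir.get(pref_dir, np.nan),
            "null_mean_spikes": by_dir.get(null_dir, np.nan),
        })
    out = pd.concat(tables, ignore_index=True)
    out.attrs["summary"] = pd.DataFrame(summary_rows)
    if config.out_dir:
        d = Path(config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        out.to_csv(d / "velocity_sweep_counts.csv", index=False)
        out.attrs["summary"].to_csv(d / "velocity_sweep_summary.csv",
                                    index=False)
    return out


def measure_ei_offset(
    cell: Cell,
    sites: Sequence[SynapseSite],
    tuning: dict[str, DirectionalTuning],
    direction_deg: float,
    velocity_um_s: float = 1000.0,
    trials: int = 200,
    seed: int = 0,
    baseline_ms: float = 200.0,
    hold_exc_mv: float = -60.0,
    hold_inh_mv: float = 0.0,
    smooth_ms: float = 10.0,
    initial_window_ms: float = 50.0,
):
    """E/I temporal offset for one direction by the voltage-clamp protocol.

    Runs the ideal-space-clamp protocol at the inhibitory reversal
    (isolating the EPSC) and at 0 mV (isolating the IPSC) for the same bar
    sweep, averages the traces over release seeds, and applies the 20-80%
    rise-fit onset estimator to both.  Release is stochastic; averaging
    recovers the expected conductance profile, and because the clamp
    current is linear in the events all trials run as one merged
    simulation.  The bar starts far enough out to leave ``baseline_ms`` of
    quiet baseline, and both fits are confined to the initial response — an
    ``initial_window_ms`` window opening at the earlier (excitatory) onset
    — so the slowly accumulating late current of the full sweep does not
    redefine the rise amplitude.  Returns an
    :class:`~dscircuit.ephys_analysis.OffsetEstimate`.
    """
    from .ephys_analysis import OffsetEstimate, onset_latency

    max_off = max(max(abs(t.pOff), abs(t.nOff)) for t in tuning.values())
    radius = cell.morphology.arbor_radius
    start = -(radius + max_off + 10.0 + velocity_um_s * baseline_ms / 1000.0)
    stim = BarStimulus(direction_deg=direction_deg,
                       velocity_um_s=velocity_um_s,
                       start_position_um=start)
    schedules = [
        activation_schedule(stim, sites, tuning,
                            seed=(seed + 31 * trial) % (2 ** 31))
        for trial in range(trials)
    ]
    duration = schedules[0].last_time_ms + 200.0
    epsc = cell.run_voltage_clamp(schedules, hold_exc_mv, duration,
                                  metadata={"direction_deg": direction_deg,
                                            "n_trials": trials})
    epsc.values /= trials
    ipsc = cell.run_voltage_clamp(schedules, hold_inh_mv, duration,
                                  metadata={"direction_deg": direction_deg,
                                            "n_trials": trials})
    ipsc.values /= trials
    # fit each current over its OWN initial response: the window opens at
    # the trace's low-threshold (2% of max) crossing and spans
    # ``initial_window_ms``.  Both fits then share the same early-rise
    # geometry (the arbor-entry chord growth), so their extrapolation biases
    # cancel in the difference, and the later glutamatergic build-up cannot
    # contaminate the cholinergic onset fit.
    from scipy.ndimage import gaussian_filter1d

    def initial_window_end(rec: Recording) -> float:
        dt = rec.dt_ms
        yv = rec.values.astype(float)
        base = float(np.mean(yv[: int(baseline_ms / dt)]))
        sv = np.abs(yv - base)
        if smooth_ms > 0:
            sv = gaussian_filter1d(sv, smooth_ms / dt, mode="nearest")
        t_low = float(np.argmax(sv >= 0.02 * sv.max())) * dt
        return t_low + initial_window_ms

    kw = dict(baseline_window_ms=baseline_ms, anchor="rise",
              smooth_ms=smooth_ms)
    efit = onset_latency(epsc, t_max_ms=initial_window_end(epsc), **kw)
    ifit = onset_latency(ipsc, t_max_ms=initial_window_end(ipsc), **kw)
    off = ifit.onset_ms - efit.onset_ms
    return OffsetEstimate(
        excitation_onset_ms=efit.onset_ms, inhibition_onset_ms=ifit.onset_ms,
        offset_ms=off, clamped_offset_ms=max(off, 0.0),
        excitation_fit=efit, inhibition_fit=ifit)


def _tuning_json(t: TuningResult | None) -> dict | None:
    if t is None:
        return None
    return {"dsi": t.dsi, "preferred_angle_deg": t.preferred_angle_deg,
            "sd_dsi": t.sd_dsi, "sd_angle_deg": t.sd_angle_deg}


def _write_dissection(out_dir: Path, results: dict[str, dict]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {}
    for name, res in results.items():
        res["counts"].to_csv(out_dir / f"dissection_{name}_counts.csv",
                             index=False)
        report[name] = {
            "tuning": _tuning_json(res["tuning"]),
            "early": _tuning_json(res["early"]),
            "peak": _tuning_json(res["peak"]),
        }
    (out_dir / "dissection_report.json").write_text(json.dumps(report, indent=1))
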
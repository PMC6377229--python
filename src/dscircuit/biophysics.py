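"""Conductance-based compartmental DSGC: active dendrites, synapses, clamps.

Region-specific channel densities (mS/cm², soma / primary dendrite /
terminal dendrite): sodium 150/150/30, potassium rectifier 70/70/35, slow
delayed rectifier 3/0.8/0.4.  Passive: 1 µF/cm² membrane capacitance,
100 Ωcm axial resistivity, leak reversing at −60 mV.  The leak density
default (0.05 mS/cm²) gives a 20 ms membrane time constant.

Two recording modes mirror the experimental configurations:

* current clamp — free somatic voltage, spikes detected by upward threshold
  crossing (−20 mV, 1 ms lockout); dendrites are active, so inputs are
  processed via dendritic spikes.
* voltage clamp — Na/K conductances blocked and the cell held at a fixed
  potential under an ideal space clamp; holding at the inhibitory reversal
  isolates excitation (EPSC), holding at 0 mV (the excitatory reversal)
  isolates inhibition (IPSC).

Membrane/channel noise is modelled as an additive Ornstein-Uhlenbeck current
per compartment with area-scaled SD and a hard off switch for deterministic
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._integrator import exp2_norm_factor, integrate
from .circuit_geometry import (
    SOMA,
    TRANSMITTERS,
    ActivationSchedule,
    Morphology,
    SynapseSite,
)
from .recording import Recording

__all__ = ["BiophysicsConfig", "Cell", "build_cell", "detect_spikes",
            "DEFAULT_DENSITIES"]

UM2_TO_CM2 = 1e-8

#: mS/cm² by region: (sodium, potassium rectifier, slow delayed rectifier)
DEFAULT_DENSITIES: dict[str, tuple[float, float, float]] = {
    "soma": (150.0, 70.0, 3.0),
    "primary_dendrite": (150.0, 70.0, 0.8),
    "terminal_dendrite": (30.0, 35.0, 0.4),
}


@dataclass(frozen=True)
class BiophysicsConfig:
    membrane_capacitance_uf_cm2: float = 1.0
    axial_resistivity_ohm_cm: float = 100.0
    leak_reversal_mv: float = -60.0
    leak_density_ms_cm2: float = 0.05
    channel_densities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    e_na_mv: float = 50.0
    e_k_mv: float = -77.0
    dt_ms: float = 0.025
    gate_voltage_shift_mv: float = 13.0
    noise_sd_ma_cm2: float = 0.005  # OU current density SD; 0 disables
    noise_tau_ms: float = 5.0
    spike_threshold_mv: float = -20.0
    refractory_ms: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.dt_ms <= 0.05):
            raise ValueError("dt must be in (0, 0.05] ms")
        for region, dens in self.channel_densities.items():
            if region not in DEFAULT_DENSITIES:
                raise ValueError(f"unknown region {region!r}")
            if any(d < 0 for d in dens):
                raise ValueError("channel densities must be >= 0")
        if self.leak_density_ms_cm2 < 0 or self.noise_sd_ma_cm2 < 0:
            raise ValueError("leak density and noise SD must be >= 0")


def detect_spikes(v_mv: np.ndarray, dt_ms: float, threshold_mv: float = -20.0,
                  refractory_ms: float = 1.0, t0_ms: float = 0.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout."""
    above = v_mv >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -math.inf
    for idx in crossings:
        t = t0_ms + idx * dt_ms
        if t - last >= refractory_ms:
            times.append(t)
            last = t
    return np.asarray(times)


class Cell:
    """A simulatable DSGC built from a morphology, synapse sites and a
    biophysics config.  Use :func:`build_cell` to construct."""

    def __init__(self, morphology: Morphology, sites: Sequence[SynapseSite],
                 config: BiophysicsConfig = BiophysicsConfig()):
        self.morphology = morphology
        self.sites = list(sites)
        self.config = config
        comps = morphology.compartments
        n = len(comps)
        by_id = {c.id: i for i, c in enumerate(comps)}
        if list(by_id) != list(range(n)):
            raise ValueError("compartment ids must be consecutive from 0")
        for s in self.sites:
            if s.compartment_id not in by_id:
                raise ValueError(f"synapse site {s.site_id} on missing compartment")

        cfg = config
        self.parent = np.array([c.parent_id for c in comps], dtype=np.int64)
        area_um2 = np.array([
            math.pi * c.diameter ** 2 if c.region == SOMA
            else math.pi * c.diameter * max(c.length, 1e-3)
            for c in comps
        ])
        area_cm2 = area_um2 * UM2_TO_CM2
        self.area_cm2 = area_cm2
        # nF = µF/cm² * cm² * 1e3
        self.cm_nf = cfg.membrane_capacitance_uf_cm2 * area_cm2 * 1e3
        # µS = mS/cm² * cm² * 1e3
        self.g_leak_us = cfg.leak_density_ms_cm2 * area_cm2 * 1e3
        gna = np.zeros(n)
        gkdr = np.zeros(n)
        gkm = np.zeros(n)
        for i, c in enumerate(comps):
            dna, dk, dkm = cfg.channel_densities[c.region]
            gna[i] = dna * area_cm2[i] * 1e3
            gkdr[i] = dk * area_cm2[i] * 1e3
            gkm[i] = dkm * area_cm2[i] * 1e3
        self.gbar_na_us, self.gbar_kdr_us, self.gbar_km_us = gna, gkdr, gkm

        # axial coupling: series sum of the two half-compartment resistances
        g_ax = np.zeros(n)
        for i, c in enumerate(comps):
            if c.parent_id < 0:
                continue
            r = self._half_axial_resistance(c)
            r += self._half_axial_resistance(comps[c.parent_id])
            g_ax[i] = 1.0 / r if r > 0 else 0.0
        self.g_ax_us = g_ax

        self.noise_sd_na = cfg.noise_sd_ma_cm2 * area_cm2 * 1e6  # mA -> nA

        # receptor kinetics, shared per transmitter (taken from the sites)
        ref = self.sites[0].receptors if self.sites else None
        self.tau_r = np.array([ref[t].rise_ms if ref else 1.0
                               for t in TRANSMITTERS])
        self.tau_d = np.array([ref[t].decay_ms if ref else 10.0
                               for t in TRANSMITTERS])
        self.e_rev = np.array([ref[t].reversal_mv if ref else 0.0
                               for t in TRANSMITTERS])
        self._site_comp = {s.site_id: s.compartment_id for s in self.sites}
        self._site_gmax = {
            s.site_id: {t: s.receptors[t].gmax_ns for t in TRANSMITTERS}
            for s in self.sites
        }
        self._norm = np.array([exp2_norm_factor(self.tau_r[k], self.tau_d[k])
                               for k in range(len(TRANSMITTERS))])

    def _half_axial_resistance(self, comp) -> float:
        """Half-compartment axial resistance in MΩ-equivalent (1/µS)."""
        if comp.region == SOMA or comp.length <= 0:
            return 0.0
        ra = self.config.axial_resistivity_ohm_cm
        l_cm = (comp.length / 2.0) * 1e-4
        a_cm2 = math.pi * (comp.diameter * 1e-4) ** 2 / 4.0
        return (ra * l_cm / a_cm2) * 1e-6   # Ω -> 1/µS

    @property
    def n_compartments(self) -> int:
        return len(self.morphology.compartments)

    @property
    def membrane_time_constant_ms(self) -> float:
        return (self.config.membrane_capacitance_uf_cm2
                / self.config.leak_density_ms_cm2)

    # -- schedule to event arrays -----------------------------------------

    def _event_arrays(self, schedule, n_steps: int, dt: float):
        schedules = ([] if schedule is None
                     else [schedule] if isinstance(schedule, ActivationSchedule)
                     else list(schedule))
        steps, comps, types, weights = [], [], [], []
        tindex = {t: k for k, t in enumerate(TRANSMITTERS)}
        for sched in schedules:
            for ev in sched.released_events():
                step = int(round(ev.scheduled_time_ms / dt))
                if step < 1:
                    step = 1
                if step > n_steps:
                    continue
                k = tindex[ev.transmitter]
                w = self._site_gmax[ev.site_id][ev.transmitter] * 1e-3  # nS->µS
                if w <= 0.0:
                    continue
                steps.append(step)
                comps.append(self._site_comp[ev.site_id])
                types.append(k)
                weights.append(w * self._norm[k])
        order = np.argsort(np.asarray(steps, dtype=np.int64), kind="stable")
        return (np.asarray(steps, dtype=np.int64)[order],
                np.asarray(comps, dtype=np.int64)[order],
                np.asarray(types, dtype=np.int64)[order],
                np.asarray(weights, dtype=float)[order])

    def _run(self, schedule, duration_ms, *, clamp=False, hold_mv=0.0,
             noise=True, noise_seed=0, block_na_k=False, inject=None):
        cfg = self.config
        dt = cfg.dt_ms
        n_steps = int(round(duration_ms / dt))
        ev = self._event_arrays(schedule, n_steps, dt)
        noise_sd = self.noise_sd_na if (noise and cfg.noise_sd_ma_cm2 > 0) \
            else np.zeros(self.n_compartments)
        zeros = np.zeros(self.n_compartments)
        gna = zeros if block_na_k else self.gbar_na_us
        gkdr = zeros if block_na_k else self.gbar_kdr_us
        gkm = zeros if block_na_k else self.gbar_km_us
        if inject is None:
            inj = (0, 0, 0, 0.0)
        else:
            amp_na, t_on, t_off = inject
            inj = (0, int(round(t_on / dt)), int(round(t_off / dt)), amp_na)
        v_init = cfg.leak_reversal_mv   # dendrites start at rest; the
        # integrator pins the soma to the holding potential in clamp mode
        v_soma, i_clamp = integrate(
            self.parent, self.g_ax_us, self.cm_nf, self.g_leak_us,
            cfg.leak_reversal_mv, gna, gkdr, gkm, cfg.e_na_mv, cfg.e_k_mv,
            ev[0], ev[1], ev[2], ev[3],
            self.tau_r, self.tau_d, self.e_rev,
            n_steps, dt, v_init, cfg.gate_voltage_shift_mv, clamp, hold_mv,
            noise_sd, cfg.noise_tau_ms, int(noise_seed) % (2 ** 31),
            inj[0], inj[1], inj[2], inj[3],
            0,
        )
        if np.any(np.isnan(v_soma)):
            gmax = float(max(self.gbar_na_us.max(), self.g_ax_us.max()))
            raise RuntimeError(
                f"numerical instability (NaN voltage): dt={dt} ms, "
                f"max conductance {gmax:.3g} µS — reduce dt")
        return v_soma, i_clamp

    # -- public recording modes -------------------------------------------

    def run_current_clamp(
        self, schedule: ActivationSchedule | None, duration_ms: float,
        noise_seed: int = 0, noise: bool = True,
        inject: tuple[float, float, float] | None = None,
        metadata: dict | None = None,
    ) -> tuple[Recording, Recording]:
        """Free-running somatic voltage; returns (spike_times, voltage)."""
        if schedule is not None and schedule.events:
            tmax = max(e.scheduled_time_ms for e in schedule.released_events()
                       ) if schedule.released_events() else 0.0
            if tmax > duration_ms:
                raise ValueError("schedule extends beyond recording duration")
        v_soma, _ = self._run(schedule, duration_ms, noise=noise,
                              noise_seed=noise_seed, inject=inject)
        cfg = self.config
        spikes = detect_spikes(v_soma, cfg.dt_ms, cfg.spike_threshold_mv,
                               cfg.refractory_ms)
        meta = dict(metadata or {})
        meta.update(mode="current_clamp", noise_seed=noise_seed, noise=noise)
        return (
            Recording(mode="spike_times", spike_times_ms=spikes, metadata=meta),
            Recording(mode="membrane_voltage", dt_ms=cfg.dt_ms, values=v_soma,
                      metadata=meta),
        )

    def run_voltage_clamp(
        self, schedule, hold_mv: float,
        duration_ms: float, noise: bool = False, noise_seed: int = 0,
        metadata: dict | None = None,
    ) -> Recording:
        """Clamp current (pA, outward positive) with Na/K blocked.

        ``schedule`` may be a single :class:`ActivationSchedule` or a
        sequence of them: under the ideal clamp the current is linear in the
        events, so passing N release-seed schedules yields N times the
        trial-averaged current (divide by N to average — see
        ``experiments.measure_ei_offset``)."""
        if not math.isfinite(hold_mv):
            raise ValueError("holding potential must be finite")
        _, i_clamp = self._run(schedule, duration_ms, clamp=True,
                               hold_mv=hold_mv, noise=noise,
                               noise_seed=noise_seed, block_na_k=True)
        meta = dict(metadata or {})
        meta.update(mode="voltage_clamp", hold_mv=hold_mv)
        return Recording(mode="voltage_clamp_current", dt_ms=self.config.dt_ms,
                         values=i_clamp * 1e3,  # nA -> pA
                         hold_potential_mv=hold_mv, metadata=meta)


def build_cell(morphology: Morphology, synapse_sites: Sequence[SynapseSite],
               biophysics_config: BiophysicsConfig = BiophysicsConfig()) -> Cell:
    """Assemble a simulatable cell (validates regions and synapse targets)."""
    return Cell(morphology, synapse_sites, biophysics_config)
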
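"""Procedural DSGC arbor, synapse placement, and moving-bar activation schedules.

The model cell is a planar dendritic arbor (soma at the origin, coordinates in
µm, directions measured counter-clockwise from the +x axis).  Tri-receptor
synapses (AMPA / nicotinic / GABA_A) sit on terminal dendritic branches.  A
bar sweeping across the arbor activates each synapse when its leading edge
crosses the synapse position, advanced by a direction-dependent spatial
offset: the synapse's effective receptive field is displaced toward the
stimulus entry side, so activation happens ``offset / velocity`` earlier.

Release probability (Pr) and spatial offset follow sigmoidal tuning curves of
the angular distance between the stimulus direction and the cell's preferred
axis (0° = preferred, 180° = null):

    Pr(a)     = pPr + (nPr - pPr) * (1 - span / (1 + exp((a - 91.0) / 25.0)))
    offset(a) = pOff - (pOff - nOff) * (1 - span / (1 + exp((a - 74.69) / 24.36)))

with span = 0.98.  Cholinergic inputs are symmetric (constant Pr, constant
~50 µm offset), glutamatergic inputs have no offset, and GABAergic inputs are
strongly asymmetric (Pr ~0.012 preferred → ~0.5 null, offset ~0 → ~50 µm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SOMA",
    "PRIMARY",
    "TERMINAL",
    "TRANSMITTERS",
    "Compartment",
    "Morphology",
    "ReceptorSpec",
    "SynapseSite",
    "DirectionalTuning",
    "BarStimulus",
    "ActivationEvent",
    "ActivationSchedule",
    "ArborConfig",
    "angle_distance",
    "release_probability",
    "spatial_offset",
    "generate_arbor",
    "place_synapses",
    "activation_schedule",
    "default_transmitter_tuning",
    "DEFAULT_RECEPTORS",
]

SOMA = "soma"
PRIMARY = "primary_dendrite"
TERMINAL = "terminal_dendrite"

#: transmitter names, in the order used throughout the package
TRANSMITTERS = ("glutamate", "acetylcholine", "gaba")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """One cable segment: ``xy`` is the distal end; the proximal end is the
    parent's distal end (the soma is a point at its own coordinate)."""

    id: int
    parent_id: int          # -1 for the soma root
    xy: tuple[float, float]  # µm
    diameter: float          # µm
    length: float            # µm (0 for the soma; treated as a sphere)
    region: str

    def __post_init__(self):
        if self.region not in (SOMA, PRIMARY, TERMINAL):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class Morphology:
    compartments: tuple[Compartment, ...]
    arbor_radius: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        comps = self.compartments
        roots = [c for c in comps if c.parent_id == -1]
        if len(roots) != 1 or roots[0].region != SOMA:
            raise ValueError("morphology must have exactly one soma root")
        ids = {c.id for c in comps}
        if len(ids) != len(comps):
            raise ValueError("duplicate compartment ids")
        children: dict[int, int] = {c.id: 0 for c in comps}
        for c in comps:
            if c.parent_id != -1:
                if c.parent_id not in ids:
                    raise ValueError(f"compartment {c.id} has missing parent")
                if c.parent_id >= c.id:
                    raise ValueError("parent ids must precede children (tree order)")
                children[c.parent_id] += 1
        for c in comps:
            if c.region == TERMINAL and children[c.id] > 0:
                raise ValueError("terminal_dendrite compartments must be leaves")
            if c.region != SOMA:
                r = math.hypot(*c.xy)
                if r > self.arbor_radius + 1e-6:
                    raise ValueError("dendrite extends beyond arbor_radius")

    @property
    def terminal_compartments(self) -> list[Compartment]:
        return [c for c in self.compartments if c.region == TERMINAL]

    def compartment(self, comp_id: int) -> Compartment:
        return self.compartments[comp_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "arbor_radius": self.arbor_radius,
                "compartments": [
                    {
                        "id": c.id,
                        "parent_id": c.parent_id,
                        "x": c.xy[0],
                        "y": c.xy[1],
                        "diameter": c.diameter,
                        "length": c.length,
                        "region": c.region,
                    }
                    for c in self.compartments
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Morphology":
        d = json.loads(text)
        comps = tuple(
            Compartment(c["id"], c["parent_id"], (c["x"], c["y"]),
                        c["diameter"], c["length"], c["region"])
            for c in d["compartments"]
        )
        return cls(comps, d["arbor_radius"])


@dataclass(frozen=True)
class ReceptorSpec:
    """Bi-exponential conductance kinetics for one receptor class."""

    rise_ms: float
    decay_ms: float
    gmax_ns: float
    reversal_mv: float

    def __post_init__(self):
        if not self.rise_ms < self.decay_ms:
            raise ValueError("rise time constant must be < decay time constant")
        if self.gmax_ns < 0:
            raise ValueError("peak conductance must be >= 0")


#: default miniature-event-like kinetics; peak conductances are model
#: calibration constants (see docs/methods.md), all overridable.
DEFAULT_RECEPTORS: dict[str, ReceptorSpec] = {
    "glutamate": ReceptorSpec(rise_ms=0.5, decay_ms=40.0, gmax_ns=2.5, reversal_mv=0.0),
    "acetylcholine": ReceptorSpec(rise_ms=1.0, decay_ms=25.0, gmax_ns=2.5, reversal_mv=0.0),
    "gaba": ReceptorSpec(rise_ms=0.5, decay_ms=60.0, gmax_ns=10.0, reversal_mv=-60.0),
}


@dataclass(frozen=True)
class SynapseSite:
    site_id: int
    compartment_id: int
    position: tuple[float, float]  # µm
    receptors: dict[str, ReceptorSpec] = field(
        default_factory=lambda: dict(DEFAULT_RECEPTORS))

    def __post_init__(self):
        missing = set(TRANSMITTERS) - set(self.receptors)
        if missing:
            raise ValueError(f"site {self.site_id} missing receptors {missing}")


@dataclass(frozen=True)
class DirectionalTuning:
    """Sigmoidal direction tuning of release probability and spatial offset.

    A symmetric (non-direction-selective) input is the degenerate case
    ``pPr == nPr`` and/or ``pOff == nOff``.
    """

    pPr: float
    nPr: float
    pOff: float   # µm, preferred-direction spatial offset
    nOff: float   # µm, null-direction spatial offset
    pr_midpoint_deg: float = 91.0
    pr_slope_deg: float = 25.0
    off_midpoint_deg: float = 74.69
    off_slope_deg: float = 24.36
    span: float = 0.98

    def __post_init__(self):
        for p in (self.pPr, self.nPr):
            if not 0.0 <= p <= 1.0:
                raise ValueError("release probabilities must lie in [0, 1]")
        for m in (self.pr_midpoint_deg, self.off_midpoint_deg):
            if not 0.0 < m < 180.0:
                raise ValueError("sigmoid midpoints must lie in (0, 180)")
        if self.pr_slope_deg <= 0 or self.off_slope_deg <= 0:
            raise ValueError("sigmoid slopes must be positive")


@dataclass(frozen=True)
class BarStimulus:
    """A bar (leading edge of infinite lateral extent, perpendicular to the
    motion axis) sweeping across the retinal plane.

    ``start_position`` is the leading-edge coordinate (µm) along the motion
    axis at t = 0; it must put the edge outside the arbor plus the largest
    spatial offset so that no synapse is active at t = 0.
    """

    direction_deg: float
    velocity_um_s: float
    preferred_axis_deg: float = 0.0
    bar_width_um: float = 200.0
    start_position_um: float = -250.0

    def __post_init__(self):
        if self.velocity_um_s <= 0:
            raise ValueError("velocity must be positive")

    @property
    def angle_distance_deg(self) -> float:
        return angle_distance(self.direction_deg, self.preferred_axis_deg)


@dataclass(frozen=True)
class ActivationEvent:
    site_id: int
    transmitter: str
    scheduled_time_ms: float
    released: bool
    pr_used: float
    spatial_offset_um: float


@dataclass(frozen=True)
class ActivationSchedule:
    trial_id: int
    seed: int
    events: tuple[ActivationEvent, ...]

    def __post_init__(self):
        seen = set()
        for ev in self.events:
            if not math.isfinite(ev.scheduled_time_ms):
                raise ValueError("scheduled times must be finite")
            if ev.released and ev.pr_used <= 0:
                raise ValueError("release with Pr_used <= 0")
            key = (ev.site_id, ev.transmitter)
            if key in seen:
                raise ValueError(f"duplicate event for {key}")
            seen.add(key)

    def released_events(self) -> list[ActivationEvent]:
        return [e for e in self.events if e.released]

    @property
    def last_time_ms(self) -> float:
        return max((e.scheduled_time_ms for e in self.events), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial_id,
                "site": [e.site_id for e in self.events],
                "transmitter": [e.transmitter for e in self.events],
                "time_ms": [e.scheduled_time_ms for e in self.events],
                "released": [e.released for e in self.events],
                "pr": [e.pr_used for e in self.events],
                "offset_um": [e.spatial_offset_um for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# tuning curves
# --------------------------------------------------------------------------

def angle_distance(stimulus_direction_deg: float, preferred_axis_deg: float) -> float:
    """Absolute wrapped angular difference in [0, 180] degrees."""
    d = (stimulus_direction_deg - preferred_axis_deg) % 360.0
    return min(d, 360.0 - d)


def _sigmoid_mix(angle_dist_deg: float, midpoint: float, slope: float,
                 span: float) -> float:
    # 0 near the preferred direction, -> span near the null direction
    return 1.0 - span / (1.0 + math.exp((angle_dist_deg - midpoint) / slope))


def release_probability(angle_dist_deg: float, tuning: DirectionalTuning) -> float:
    """Release probability at an angular distance from the preferred axis."""
    s = _sigmoid_mix(angle_dist_deg, tuning.pr_midpoint_deg,
                     tuning.pr_slope_deg, tuning.span)
    return tuning.pPr + (tuning.nPr - tuning.pPr) * s


def spatial_offset(angle_dist_deg: float, tuning: DirectionalTuning) -> float:
    """Receptive-field displacement (µm) toward the stimulus entry side."""
    s = _sigmoid_mix(angle_dist_deg, tuning.off_midpoint_deg,
                     tuning.off_slope_deg, tuning.span)
    return tuning.pOff - (tuning.pOff - tuning.nOff) * s


def default_transmitter_tuning(
    *,
    non_ds_gaba: bool = False,
    temporal_offsets: bool = True,
    glut_pr: float = 0.5,
    ach_pr: float = 0.5,
    ach_offset_um: float = 50.0,
    gaba_pPr: float = 0.012,
    gaba_nPr: float = 0.5,
    gaba_pOff: float = 0.0,
    gaba_nOff: float = 50.0,
) -> dict[str, DirectionalTuning]:
    """Per-transmitter tuning for the standard model configurations.

    ``non_ds_gaba`` clamps GABA release probability at its null value in all
    directions (the rendered-non-directional starburst configuration);
    ``temporal_offsets=False`` zeroes every spatial offset, making all three
    receptive fields co-extensive (the amplitude-asymmetry-only model).
    """
    gaba_pr_lo = gaba_nPr if non_ds_gaba else gaba_pPr
    if not temporal_offsets:
        ach_offset_um = 0.0
        gaba_pOff = gaba_nOff = 0.0
    return {
        "glutamate": DirectionalTuning(pPr=glut_pr, nPr=glut_pr, pOff=0.0, nOff=0.0),
        "acetylcholine": DirectionalTuning(
            pPr=ach_pr, nPr=ach_pr, pOff=ach_offset_um, nOff=ach_offset_um),
        "gaba": DirectionalTuning(
            pPr=gaba_pr_lo, nPr=gaba_nPr, pOff=gaba_pOff, nOff=gaba_nOff),
    }


# --------------------------------------------------------------------------
# procedural arbor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArborConfig:
    radius_um: float = 150.0
    branch_order: int = 4
    n_primary: int = 6
    segment_length_um: float = 15.0
    soma_diameter_um: float = 15.0
    primary_diameter_um: float = 1.2
    terminal_diameter_um: float = 0.7
    angle_jitter_deg: float = 8.0
    length_jitter: float = 0.1

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("arbor radius must be positive")
        if self.branch_order < 1:
            raise ValueError("branch order must be >= 1")
        if self.n_primary < 1:
            raise ValueError("need at least one primary dendrite")


def generate_arbor(config: ArborConfig = ArborConfig(), seed: int = 0) -> Morphology:
    """Seeded procedural planar arbor.

    ``n_primary`` trunks leave the soma at evenly spaced angles (plus jitter)
    and bifurcate ``branch_order - 1`` times; branches of the final order are
    single terminal compartments, earlier orders are chains of
    ``segment_length_um`` primary-dendrite segments.  Tip radii are capped at
    ``radius_um`` so the whole arbor lies inside the nominal dendritic field.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    soma_r = cfg.soma_diameter_um / 2.0
    radial_span = cfg.radius_um - soma_r
    order_len = radial_span / cfg.branch_order

    comps: list[Compartment] = [
        Compartment(0, -1, (0.0, 0.0), cfg.soma_diameter_um, 0.0, SOMA)
    ]

    def add_segmented_branch(parent_id: int, start: np.ndarray,
                             heading: float, length: float,
                             diameter: float, region: str) -> int:
        """Append a branch as one (terminal) or several chained compartments;
        return the id of its most distal compartment."""
        if region == TERMINAL:
            n_seg = 1
        else:
            n_seg = max(1, int(round(length / cfg.segment_length_um)))
        seg_vec = np.array([math.cos(heading), math.sin(heading)])
        pid = parent_id
        pos = start.copy()
        for _ in range(n_seg):
            seg_len = length / n_seg
            new_pos = pos + seg_vec * seg_len
            r = np.linalg.norm(new_pos)
            if r > cfg.radius_um:           # cap tips at the arbor boundary
                new_pos *= cfg.radius_um / r
                seg_len = float(np.linalg.norm(new_pos - pos))
            cid = len(comps)
            comps.append(Compartment(cid, pid, (float(new_pos[0]), float(new_pos[1])),
                                     diameter, seg_len, region))
            pid = cid
            pos = new_pos
        return pid

    # (parent_id, tip position, heading) per branch of the current order
    frontier: list[tuple[int, np.ndarray, float]] = []
    for k in range(cfg.n_primary):
        heading = math.radians(360.0 * k / cfg.n_primary
                               + rng.uniform(-cfg.angle_jitter_deg, cfg.angle_jitter_deg))
        start = soma_r * np.array([math.cos(heading), math.sin(heading)])
        frontier.append((0, start, heading))

    for order in range(1, cfg.branch_order + 1):
        terminal = order == cfg.branch_order
        region = TERMINAL if terminal else PRIMARY
        diameter = cfg.terminal_diameter_um if terminal else cfg.primary_diameter_um
        next_frontier: list[tuple[int, np.ndarray, float]] = []
        for parent_id, start, heading in frontier:
            length = order_len * (1.0 + rng.uniform(-cfg.length_jitter,
                                                    cfg.length_jitter))
            tip_id = add_segmented_branch(parent_id, start, heading,
                                          length, diameter, region)
            if not terminal:
                tip = np.array(comps[tip_id].xy)
                spread = math.radians(45.0 / order)
                for sign in (-1.0, 1.0):
                    child_heading = (heading + sign * spread
                                     + math.radians(rng.uniform(
                                         -cfg.angle_jitter_deg, cfg.angle_jitter_deg)))
                    next_frontier.append((tip_id, tip, child_heading))
        frontier = next_frontier

    return Morphology(tuple(comps), cfg.radius_um)


def place_synapses(
    morphology: Morphology,
    target_spacing_um: float = 10.0,
    seed: int = 0,
    receptors: dict[str, ReceptorSpec] | None = None,
) -> list[SynapseSite]:
    """Place tri-receptor synapses along every terminal dendritic branch.

    Each terminal branch of length L gets ``max(1, round(L / spacing))``
    evenly spaced sites (small seeded jitter), so spacing stays within ±50%
    of the target and even short branches carry at least one site.
    """
    if target_spacing_um <= 0:
        raise ValueError("target spacing must be positive")
    receptors = dict(receptors or DEFAULT_RECEPTORS)
    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in morphology.compartments}
    sites: list[SynapseSite] = []
    for comp in morphology.terminal_compartments:
        prox = np.array(by_id[comp.parent_id].xy)
        dist = np.array(comp.xy)
        n = max(1, int(round(comp.length / target_spacing_um)))
        for i in range(n):
            frac = (i + 0.5) / n + rng.uniform(-0.1, 0.1) / n
            frac = min(max(frac, 0.0), 1.0)
            pos = prox + frac * (dist - prox)
            sites.append(SynapseSite(len(sites), comp.id,
                                     (float(pos[0]), float(pos[1])), receptors))
    return sites


# --------------------------------------------------------------------------
# activation schedule
# --------------------------------------------------------------------------

def activation_schedule(
    stimulus: BarStimulus,
    sites: Sequence[SynapseSite],
    per_transmitter_tuning: dict[str, DirectionalTuning],
    seed: int = 0,
    trial_id: int = 0,
) -> ActivationSchedule:
    """Per-site, per-transmitter activation times and Bernoulli release draws.

    The bar's leading edge crosses the projection of each synapse position on
    the motion axis at ``(proj - start) / v``; the spatial offset advances
    that crossing by ``offset / v`` (receptive field displaced toward the
    entry side).  One Bernoulli(Pr) draw per (site, transmitter) decides
    release.
    """
    theta = math.radians(stimulus.direction_deg)
    axis = np.array([math.cos(theta), math.sin(theta)])
    angle_dist = stimulus.angle_distance_deg
    v = stimulus.velocity_um_s

    max_off = max(
        max(abs(t.pOff), abs(t.nOff)) for t in per_transmitter_tuning.values()
    )
    projections = [float(np.dot(np.array(s.position), axis)) for s in sites]
    if projections and stimulus.start_position_um > min(projections) - max_off:
        raise ValueError(
            "bar must start outside the arbor plus the largest spatial offset "
            f"(start {stimulus.start_position_um} µm, nearest synapse "
            f"{min(projections) - max_off:.1f} µm)")

    rng = np.random.default_rng(seed)
    events: list[ActivationEvent] = []
    for transmitter in TRANSMITTERS:
        tuning = per_transmitter_tuning[transmitter]
        pr = release_probability(angle_dist, tuning)
        off = spatial_offset(angle_dist, tuning)
        for site, proj in zip(sites, projections):
            t_cross_ms = (proj - stimulus.start_position_um) / v * 1000.0
            t_ms = t_cross_ms - off / v * 1000.0
            released = bool(rng.random() < pr)
            events.append(ActivationEvent(site.site_id, transmitter, t_ms,
                                          released, pr, off))
    return ActivationSchedule(trial_id=trial_id, seed=seed, events=tuple(events))
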
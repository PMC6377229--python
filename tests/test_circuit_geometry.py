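"""Arbor generation, tuning sigmoids, and activation scheduling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dscircuit.circuit_geometry import (
    TRANSMITTERS,
    ActivationSchedule,
    ArborConfig,
    BarStimulus,
    DirectionalTuning,
    Morphology,
    SynapseSite,
    activation_schedule,
    angle_distance,
    default_transmitter_tuning,
    generate_arbor,
    place_synapses,
    release_probability,
    spatial_offset,
)

GABA_TUNING = DirectionalTuning(pPr=0.012, nPr=0.5, pOff=0.0, nOff=50.0)


# ---------------------------------------------------------------- sigmoids

@pytest.mark.parametrize("a, b, expected", [
    (90.0, 90.0, 0.0),
    (270.0, 90.0, 180.0),
    (350.0, 10.0, 20.0),
    (10.0, 350.0, 20.0),
    (-45.0, 45.0, 90.0),
    (720.0 + 30.0, 30.0, 0.0),
])
def test_angle_distance_wraps(a, b, expected):
    assert angle_distance(a, b) == pytest.approx(expected)


def _sigmoid_oracle(angle, lo, hi, mid, slope, span=0.98):
    # independent direct evaluation of the printed tuning equation
    mix = 1.0 - span / (1.0 + math.exp((angle - mid) / slope))
    return lo + (hi - lo) * mix


@pytest.mark.parametrize("angle, expected", [
    (0.0, 0.0339938),
    (91.0, 0.26088),
    (180.0, 0.4867755),
])
def test_release_probability_matches_hand_evaluation(angle, expected):
    assert release_probability(angle, GABA_TUNING) == pytest.approx(
        expected, abs=1e-6)
    assert release_probability(angle, GABA_TUNING) == pytest.approx(
        _sigmoid_oracle(angle, 0.012, 0.5, 91.0, 25.0), abs=1e-12)


@pytest.mark.parametrize("angle, expected", [
    (0.0, 3.1818622),
    (74.69, 25.5),
    (180.0, 49.3588054),
])
def test_spatial_offset_matches_hand_evaluation(angle, expected):
    assert spatial_offset(angle, GABA_TUNING) == pytest.approx(
        expected, abs=1e-6)


@given(st.floats(min_value=0.0, max_value=180.0))
def test_degenerate_tuning_is_constant(angle):
    flat = DirectionalTuning(pPr=0.5, nPr=0.5, pOff=20.0, nOff=20.0)
    assert release_probability(angle, flat) == pytest.approx(0.5)
    assert spatial_offset(angle, flat) == pytest.approx(20.0)


@given(st.floats(min_value=0.0, max_value=180.0),
       st.floats(min_value=0.0, max_value=180.0))
def test_release_probability_monotone_when_preferred_low(a1, a2):
    lo, hi = sorted((a1, a2))
    assert (release_probability(lo, GABA_TUNING)
            <= release_probability(hi, GABA_TUNING) + 1e-12)


def test_tuning_validation():
    with pytest.raises(ValueError):
        DirectionalTuning(pPr=-0.1, nPr=0.5, pOff=0.0, nOff=50.0)
    with pytest.raises(ValueError):
        DirectionalTuning(pPr=0.1, nPr=0.5, pOff=0.0, nOff=50.0,
                          pr_slope_deg=0.0)


# ---------------------------------------------------------------- arbor

def test_arbor_seeded_determinism():
    cfg = ArborConfig()
    a = generate_arbor(cfg, seed=1)
    b = generate_arbor(cfg, seed=1)
    assert a.compartments == b.compartments
    assert a.compartments != generate_arbor(cfg, seed=2).compartments


def test_arbor_degenerate_single_order():
    m = generate_arbor(ArborConfig(branch_order=1, n_primary=5), seed=1)
    non_soma = [c for c in m.compartments if c.region != "soma"]
    assert len(non_soma) == 5
    assert all(c.region == "terminal_dendrite" for c in non_soma)


def test_arbor_tips_cover_all_quadrants(arbor):
    tips = np.array([c.xy for c in arbor.terminal_compartments])
    angles = np.rad2deg(np.arctan2(tips[:, 1], tips[:, 0])) % 360.0
    # terminal tips distributed over the full circle
    assert np.all(np.histogram(angles, bins=8, range=(0, 360))[0] > 0)


def test_arbor_invalid_config_rejected():
    with pytest.raises(ValueError):
        ArborConfig(radius_um=-1.0)
    with pytest.raises(ValueError):
        ArborConfig(branch_order=0)


def test_morphology_tree_invariants_enforced(arbor):
    # round trip preserves validity; tampering breaks it
    again = Morphology.from_json(arbor.to_json())
    assert again.compartments == arbor.compartments
    bad = [c for c in arbor.compartments]
    bad[5] = type(bad[5])(bad[5].id, bad[5].id, bad[5].xy, bad[5].diameter,
                          bad[5].length, bad[5].region)  # self-parent
    with pytest.raises(ValueError):
        Morphology(tuple(bad), arbor.arbor_radius)


# ---------------------------------------------------------------- synapses

def test_synapse_count_follows_spacing(one_branch_morphology):
    sites = place_synapses(one_branch_morphology, 20.0, seed=0)
    assert 4 <= len(sites) <= 6          # 100 µm / 20 µm → 5 ± 1
    assert all(s.compartment_id == 1 for s in sites)
    assert all(set(s.receptors) == set(TRANSMITTERS) for s in sites)


def test_sparse_spacing_floor_rule(one_branch_morphology):
    sites = place_synapses(one_branch_morphology, 500.0, seed=0)
    assert len(sites) == 1               # at least one site per terminal branch


def test_place_synapses_deterministic(arbor):
    a = place_synapses(arbor, 10.0, seed=7)
    b = place_synapses(arbor, 10.0, seed=7)
    assert [s.position for s in a] == [s.position for s in b]
    with pytest.raises(ValueError):
        place_synapses(arbor, -1.0)


# ---------------------------------------------------------------- schedule

def _one_branch_sites(morph, positions):
    return [SynapseSite(i, 1, p) for i, p in enumerate(positions)]


def test_schedule_matches_brute_force_projection(one_branch_morphology):
    rng = np.random.default_rng(0)
    positions = [tuple(rng.uniform(-100, 100, 2)) for _ in range(10)]
    sites = _one_branch_sites(one_branch_morphology, positions)
    tuning = default_transmitter_tuning()
    stim = BarStimulus(direction_deg=30.0, velocity_um_s=1200.0,
                       preferred_axis_deg=0.0)
    sched = activation_schedule(stim, sites, tuning, seed=0)
    theta = math.radians(30.0)
    for ev in sched.events:
        x, y = positions[ev.site_id]
        proj = x * math.cos(theta) + y * math.sin(theta)
        t_expected = ((proj - stim.start_position_um)
                      - ev.spatial_offset_um) / 1200.0 * 1000.0
        assert abs(ev.scheduled_time_ms - t_expected) < 1e-9


def test_cholinergic_lead_over_glutamate(one_branch_morphology):
    """An isotropic 50 µm ACh offset advances ACh by 50 ms at 1 mm/s."""
    sites = _one_branch_sites(one_branch_morphology, [(0.0, 0.0)])
    tuning = default_transmitter_tuning()
    stim = BarStimulus(direction_deg=0.0, velocity_um_s=1000.0)
    sched = activation_schedule(stim, sites, tuning, seed=0)
    times = {e.transmitter: e.scheduled_time_ms for e in sched.events}
    assert times["glutamate"] - times["acetylcholine"] == pytest.approx(50.0)


def test_null_direction_gaba_lead(one_branch_morphology):
    """Null-direction GABA is advanced by the sigmoid's ~49.36 µm offset."""
    sites = _one_branch_sites(one_branch_morphology, [(0.0, 0.0)])
    tuning = default_transmitter_tuning()
    stim = BarStimulus(direction_deg=180.0, velocity_um_s=1000.0)
    sched = activation_schedule(stim, sites, tuning, seed=0)
    times = {e.transmitter: e.scheduled_time_ms for e in sched.events}
    assert times["glutamate"] - times["gaba"] == pytest.approx(49.359, abs=1e-2)
    pref = activation_schedule(
        BarStimulus(direction_deg=0.0, velocity_um_s=1000.0),
        sites, tuning, seed=0)
    tp = {e.transmitter: e.scheduled_time_ms for e in pref.events}
    assert tp["glutamate"] - tp["gaba"] == pytest.approx(3.182, abs=1e-2)


def test_zero_pr_never_releases(one_branch_morphology):
    sites = _one_branch_sites(one_branch_morphology,
                              [(float(x), 0.0) for x in range(-50, 51, 10)])
    tuning = default_transmitter_tuning(glut_pr=0.0)
    sched = activation_schedule(
        BarStimulus(direction_deg=0.0, velocity_um_s=1000.0),
        sites, tuning, seed=3)
    glut = [e for e in sched.events if e.transmitter == "glutamate"]
    assert glut and not any(e.released for e in glut)


def test_empirical_release_fraction(one_branch_morphology):
    """Bernoulli draws track Pr within 3 binomial SDs over 10⁴ sites."""
    n = 10_000
    sites = _one_branch_sites(one_branch_morphology, [(0.0, 0.0)] * n)
    tuning = default_transmitter_tuning()
    stim = BarStimulus(direction_deg=90.0, velocity_um_s=1000.0)
    sched = activation_schedule(stim, sites, tuning, seed=11)
    for transmitter in TRANSMITTERS:
        evs = [e for e in sched.events if e.transmitter == transmitter]
        pr = evs[0].pr_used
        frac = sum(e.released for e in evs) / n
        tol = 3.0 * math.sqrt(pr * (1 - pr) / n)
        assert abs(frac - pr) <= tol


def test_schedule_mirror_symmetry(one_branch_morphology):
    """With isotropic tuning, directions θ and −θ give mirror-image
    schedules for mirror-image site layouts."""
    pos = [(30.0, 40.0), (-20.0, 10.0), (5.0, -60.0)]
    mirrored = [(x, -y) for x, y in pos]
    tuning = {t: DirectionalTuning(pPr=1.0, nPr=1.0, pOff=10.0, nOff=10.0)
              for t in TRANSMITTERS}
    s1 = activation_schedule(
        BarStimulus(direction_deg=30.0, velocity_um_s=1000.0),
        _one_branch_sites(one_branch_morphology, pos), tuning, seed=0)
    s2 = activation_schedule(
        BarStimulus(direction_deg=-30.0, velocity_um_s=1000.0),
        _one_branch_sites(one_branch_morphology, mirrored), tuning, seed=0)
    t1 = sorted(e.scheduled_time_ms for e in s1.events)
    t2 = sorted(e.scheduled_time_ms for e in s2.events)
    assert np.allclose(t1, t2, atol=1e-9)


def test_schedule_rejects_bad_geometry(one_branch_morphology):
    sites = _one_branch_sites(one_branch_morphology, [(0.0, 0.0)])
    tuning = default_transmitter_tuning()
    with pytest.raises(ValueError):
        BarStimulus(direction_deg=0.0, velocity_um_s=0.0)
    with pytest.raises(ValueError, match="outside"):
        activation_schedule(
            BarStimulus(direction_deg=0.0, velocity_um_s=1000.0,
                        start_position_um=-10.0),
            sites, tuning, seed=0)


def test_schedule_determinism_and_csv_roundtrip(tmp_path, one_branch_morphology):
    sites = _one_branch_sites(one_branch_morphology, [(0.0, 0.0), (10.0, 5.0)])
    tuning = default_transmitter_tuning()
    stim = BarStimulus(direction_deg=45.0, velocity_um_s=1000.0)
    a = activation_schedule(stim, sites, tuning, seed=5)
    b = activation_schedule(stim, sites, tuning, seed=5)
    assert a.events == b.events
    a.to_csv(tmp_path / "sched.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "sched.csv")
    assert list(df.columns) == ["trial", "site", "transmitter", "time_ms",
                                "released", "pr", "offset_um"]
    assert len(df) == len(a.events)


def test_duplicate_events_rejected():
    from dscircuit.circuit_geometry import ActivationEvent
    ev = ActivationEvent(0, "gaba", 1.0, False, 0.5, 0.0)
    with pytest.raises(ValueError):
        ActivationSchedule(0, 0, (ev, ev))
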
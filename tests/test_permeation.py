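"""Crossing detection, flux accumulation and conductance estimation."""
import numpy as np
import pytest

from flexmd.errors import ConfigError, SelectionError
from flexmd.model import ChannelDefinition
from flexmd.permeation import (
    ELEMENTARY_CHARGE,
    bootstrap_conductance,
    cumulative_flux,
    detect_crossings,
    estimate_conductance,
)
from flexmd.synthetic import poisson_events

from conftest import make_single_ion_trajectory
from oracles import brute_force_crossings, random_z_walk


@pytest.mark.parametrize(
    "z_path, expected_dirs",
    [
        # straight traversal upward
        ([-20, -10, 0, 10, 20], [+1]),
        # partial entry and retreat: not a crossing
        ([-20, 0, -20], []),
        # periodic wrap at the box edge is not a traversal
        ([20, 44, -44, -20], []),
        # there and back again: two events, net zero
        ([-20, 5, 20, 5, -20], [+1, -1]),
        # fast single-step traversal still counts
        ([-20, 20, 20], [+1]),
        # wrap landing inside the slab, then exit downward: no event
        ([20, 44, -44, 0, -20], []),
    ],
)
def test_state_machine_paths(z_path, expected_dirs, slab_channel):
    traj = make_single_ion_trajectory(z_path)
    events = detect_crossings(traj, slab_channel, [0])
    assert [e.direction for e in events] == expected_dirs


def test_crossing_event_fields(slab_channel):
    traj = make_single_ion_trajectory([-20, -10, 0, 10, 20])
    (event,) = detect_crossings(traj, slab_channel, [0])
    assert event.species == "K"
    assert event.valence == 1
    assert event.completion_time == 4.0  # frame where z first exceeds z_hi


def test_zero_valence_ion_rejected(slab_channel):
    traj = make_single_ion_trajectory([-20, 0, 20], valence=0)
    with pytest.raises(SelectionError, match="valence 0"):
        detect_crossings(traj, slab_channel, [0])


def test_radial_gate_discards_offaxis_traversals():
    chan = ChannelDefinition(z_lo=-15, z_hi=15, voltage=150, pore_radius=6.0)
    traj = make_single_ion_trajectory([-20, -10, 0, 10, 20])
    traj.coordinates[2, 0, 0] = 10.0  # off-axis while inside the slab
    assert detect_crossings(traj, chan, [0]) == []
    traj.coordinates[2, 0, 0] = 3.0  # within the pore radius
    assert len(detect_crossings(traj, chan, [0])) == 1


def test_detector_matches_brute_force_on_random_walks(slab_channel):
    """Fuzz the state machine against the segment-compression oracle."""
    rng = np.random.default_rng(2024)
    lz = 90.0
    for _ in range(200):
        z = random_z_walk(rng, 250, lz)
        traj = make_single_ion_trajectory(z, lz=lz)
        got = [
            (int(e.completion_time), e.direction)
            for e in detect_crossings(traj, slab_channel, [0])
        ]
        expected = brute_force_crossings(z, lz, -15.0, 15.0)
        assert got == expected


# ---------------------------------------------------------------------------
# cumulative flux
# ---------------------------------------------------------------------------

def test_cumulative_flux_empty():
    flux = cumulative_flux([], np.arange(5.0))
    assert flux.total == {} and flux.net == {}


def test_cumulative_flux_counting():
    from flexmd.permeation import CrossingEvent

    ev = [
        CrossingEvent(0, "K", 1, +1, 1000.0),
        CrossingEvent(0, "K", 1, +1, 2000.0),
        CrossingEvent(0, "K", 1, +1, 3000.0),
    ]
    flux = cumulative_flux(ev, np.array([0.0, 1000.0, 2000.0, 3000.0, 4000.0]))
    assert flux.total["K"].tolist() == [0, 1, 2, 3, 3]
    assert flux.net["K"].tolist() == [0, 1, 2, 3, 3]


def test_cumulative_flux_net_vs_total():
    from flexmd.permeation import CrossingEvent

    ev = [
        CrossingEvent(0, "K", 1, +1, 1.0),
        CrossingEvent(1, "K", 1, +1, 2.0),
        CrossingEvent(2, "K", 1, -1, 3.0),
    ]
    flux = cumulative_flux(ev, np.array([4.0]))
    assert flux.total["K"][-1] == 3
    assert flux.net["K"][-1] == 1
    # |net| <= total on every prefix
    flux2 = cumulative_flux(ev, np.arange(0.0, 5.0))
    assert np.all(np.abs(flux2.net["K"]) <= flux2.total["K"])


# ---------------------------------------------------------------------------
# conductance
# ---------------------------------------------------------------------------

def _mk_events(n_up_cations=0, n_down_anions=0, spread=500.0):
    from flexmd.permeation import CrossingEvent

    ev = [
        CrossingEvent(i, "K", 1, +1, (i + 0.5) * spread / max(n_up_cations, 1))
        for i in range(n_up_cations)
    ]
    ev += [
        CrossingEvent(100 + i, "CL", -1, -1,
                      (i + 0.5) * spread / max(n_down_anions, 1))
        for i in range(n_down_anions)
    ]
    return ev


def test_conductance_hand_value_single_species(slab_channel):
    # 42 cations up in 0.5 µs at 150 mV: G = 42 q_e / (5e-7 s * 0.15 V)
    ev = _mk_events(n_up_cations=42)
    g = estimate_conductance(ev, slab_channel, total_time=500.0)
    expected = 42 * ELEMENTARY_CHARGE / 5e-7 / 0.15 * 1e12
    assert g == pytest.approx(expected, rel=1e-12)
    assert g == pytest.approx(89.72, abs=0.01)


def test_conductance_hand_value_two_species(slab_channel):
    # 10 K+ up and 10 Cl- down over 1 µs at 150 mV -> Q = 20 q_e
    ev = _mk_events(n_up_cations=10, n_down_anions=10, spread=1000.0)
    g = estimate_conductance(ev, slab_channel, total_time=1000.0)
    assert g == pytest.approx(21.36, abs=0.01)


def test_conductance_no_events_and_errors(slab_channel):
    assert estimate_conductance([], slab_channel, 100.0) == 0.0
    with pytest.raises(ConfigError):
        estimate_conductance([], slab_channel, 0.0)
    chan0 = ChannelDefinition(z_lo=-15, z_hi=15, voltage=0.0)
    with pytest.raises(ConfigError, match="voltage"):
        estimate_conductance([], chan0, 100.0)


def test_doubling_voltage_halves_conductance(slab_channel):
    ev = _mk_events(n_up_cations=30)
    g1 = estimate_conductance(ev, slab_channel, 500.0)
    chan2 = ChannelDefinition(z_lo=-15, z_hi=15, voltage=300.0)
    g2 = estimate_conductance(ev, chan2, 500.0)
    assert g2 == pytest.approx(g1 / 2)


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_single_block_has_zero_sd(slab_channel):
    ev = poisson_events(20.0, 1000.0, seed=5)
    est = bootstrap_conductance(ev, slab_channel, 1000.0, block_length=1000.0,
                                n_boot=50, seed=1)
    assert est.bootstrap_sd == pytest.approx(0.0, abs=1e-9)
    assert est.conductance == pytest.approx(
        estimate_conductance(ev, slab_channel, 1000.0)
    )


def test_bootstrap_detects_overdispersion(slab_channel):
    """Events packed into one half of the record inflate the SD beyond the
    Poisson standard error for the same event count."""
    rng = np.random.default_rng(7)
    from flexmd.permeation import CrossingEvent

    t_total = 10_000.0
    n = 200
    times = np.sort(rng.uniform(0, t_total / 2, n))  # all in the first half
    ev = [CrossingEvent(0, "K", 1, +1, float(t)) for t in times]
    est = bootstrap_conductance(ev, slab_channel, t_total,
                                block_length=t_total / 20, n_boot=400, seed=2)
    poisson_se = (
        np.sqrt(n) * ELEMENTARY_CHARGE / (t_total * 1e-9) / 0.15 * 1e12
    )
    assert est.bootstrap_sd > poisson_se


def test_bootstrap_pooling_combines_records(slab_channel):
    ev1 = poisson_events(20.0, 5000.0, seed=8)
    ev2 = poisson_events(20.0, 5000.0, seed=9)
    est = bootstrap_conductance(
        ev1, slab_channel, 5000.0, block_length=500.0, n_boot=100, seed=3,
        pooled=[(ev2, 5000.0)],
    )
    assert est.total_time == 10_000.0
    assert est.n_events == len(ev1) + len(ev2)
    pooled_g = estimate_conductance(ev1 + ev2, slab_channel, 10_000.0)
    assert est.conductance == pytest.approx(pooled_g)


def test_bootstrap_contract_errors(slab_channel):
    ev = poisson_events(20.0, 1000.0, seed=5)
    with pytest.raises(ConfigError):
        bootstrap_conductance(ev, slab_channel, 1000.0, block_length=2000.0,
                              n_boot=10, seed=0)
    with pytest.raises(ConfigError):
        bootstrap_conductance(ev, slab_channel, 1000.0, block_length=100.0,
                              n_boot=1, seed=0)


def test_bootstrap_deterministic_under_seed(slab_channel):
    ev = poisson_events(20.0, 5000.0, seed=8)
    a = bootstrap_conductance(ev, slab_channel, 5000.0, n_boot=50, seed=42)
    b = bootstrap_conductance(ev, slab_channel, 5000.0, n_boot=50, seed=42)
    assert a.bootstrap_sd == b.bootstrap_sd
    assert np.array_equal(a.replicates, b.replicates)
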
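"""Synthetic MD-like trajectories with exact ground truth.

Two generators emulate the statistical structure of the systems the
analysis modules target, so every estimator can be validated against a
known answer:

* :func:`gen_channel_trajectory` — a membrane-spanning channel along z.
  A hidden two-state Markov chain (open / constricted) gates both the
  ion-crossing rate and the pore water occupancy; crossing events are
  Poisson within each state and each event is realised as a scripted,
  monotone multi-frame ion path through the channel slab.  Ions otherwise
  idle in the reservoirs, and return trips (plus optional extra idle
  moves) happen as jumps across the periodic z boundary, which a correct
  detector must *not* count.

* :func:`gen_ligase_trajectory` — an 87-residue protein mimic with a
  rigid, metal-organised core (two Zn sites), a flexible catalytic loop
  and flexible tails.  Backbone atoms sit on a smooth self-avoiding curve
  and are displaced per frame by region-specific Gaussian noise; Zn-ligand
  geometry, a scripted ligand substitution and scripted salt bridges are
  imposed exactly.

There is no force field and no dynamics here — only scripted geometry
with calibrated randomness.  Identical seed and config give byte-identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .model import Atom, Topology, Trajectory
from .permeation import CrossingEvent

_DEFAULT_SALT_BRIDGES = [(17, 55, 0.6), (61, 43, 0.8)]


# ---------------------------------------------------------------------------
# Channel system
# ---------------------------------------------------------------------------

@dataclass
class ChannelSimConfig:
    """Study conditions for the gated-channel generator.

    Rates are per species: `rate_open`/`rate_closed` are crossing rates in
    events/µs while the hidden state is open/constricted, and the k's are
    state-switching rates in 1/µs (the 2/µs defaults give 0.5 µs mean
    dwell times, a convention for the long high/low-conductance periods).
    Voltage is applied along +z; with `p_drift` a crossing goes with the
    electric driving force (cations +z, anions −z) rather than against it.
    """

    duration: float = 10_000.0  # ns (10 µs)
    dt: float = 1.0  # ns per frame
    voltage: float = 150.0  # mV
    box: tuple[float, float, float] = (60.0, 60.0, 90.0)
    slab: tuple[float, float] = (-15.0, 15.0)
    pore_radius: float = 6.0  # Å
    n_cations: int = 20
    n_anions: int = 20
    rate_open: float = 20.0  # crossings/µs per species, open state
    rate_closed: float = 1.0  # crossings/µs per species, constricted state
    k_open_to_closed: float = 2.0  # 1/µs
    k_closed_to_open: float = 2.0  # 1/µs
    water_mean_open: float = 30.0  # pore waters, open state
    water_mean_closed: float = 5.0  # pore waters, constricted state
    p_drift: float = 0.9  # probability a crossing goes with the field
    water_coupled: bool = True  # False: water Poisson mean ignores the state
    scripted_wraps: bool = True  # add idle-ion periodic wraps
    crossing_frames: int = 5  # frames per scripted traversal (≥ 3)
    n_bulk_waters: int = 20  # waters parked outside the pore
    seed: int = 0

    def __post_init__(self):
        z_lo, z_hi = self.slab
        if not z_lo < z_hi:
            raise ConfigError(f"slab z_lo ({z_lo}) must be < z_hi ({z_hi})")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        for name in ("rate_open", "rate_closed", "k_open_to_closed",
                     "k_closed_to_open", "water_mean_open", "water_mean_closed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")
        if not 0 <= self.p_drift <= 1:
            raise ConfigError("p_drift must be in [0, 1]")
        if self.crossing_frames < 3:
            raise ConfigError("crossing_frames must be ≥ 3")
        if self.box[2] <= (z_hi - z_lo):
            raise ConfigError("box z edge must exceed the slab thickness")


@dataclass
class ChannelGroundTruth:
    """What the channel generator actually scripted."""

    events: list[CrossingEvent]
    state_series: np.ndarray  # 1 = open, 0 = constricted, per frame
    water_counts: np.ndarray  # realised in-pore water count per frame
    cation_indices: np.ndarray
    anion_indices: np.ndarray
    water_indices: np.ndarray

    def open_fraction(self) -> float:
        return float(np.mean(self.state_series))


def _simulate_two_state(rng, duration_ns, k_oc, k_co, times):
    """Continuous-time two-state chain; returns per-frame state (1=open)."""
    if k_oc == 0 and k_co == 0:
        return np.ones(len(times), dtype=int), [0.0], [1]
    switch_times = []
    switch_states = []
    t = 0.0
    state = 1  # start open
    while t < duration_ns:
        switch_times.append(t)
        switch_states.append(state)
        k = k_oc if state == 1 else k_co
        if k == 0:
            break
        t += rng.exponential(1.0 / k) * 1000.0  # µs -> ns
        state = 1 - state
    idx = np.searchsorted(switch_times, times, side="right") - 1
    return np.asarray(switch_states, dtype=int)[idx], switch_times, switch_states


def _state_intervals(switch_times, switch_states, duration_ns):
    bounds = list(switch_times) + [duration_ns]
    return [
        (bounds[i], min(bounds[i + 1], duration_ns), switch_states[i])
        for i in range(len(switch_states))
        if bounds[i] < duration_ns
    ]


class _IonScheduler:
    """Assign scripted crossings and periodic-wrap moves to a pool of ions."""

    def __init__(self, n_ions, n_frames, home_z, crossing_frames):
        if n_ions == 0:
            raise ConfigError("need at least one ion of each conducting species")
        self.n_frames = n_frames
        self.home_z = home_z  # {-1: z_below, +1: z_above}
        self.m = crossing_frames
        self.homes = [(-1 if i < (n_ions + 1) // 2 else 1) for i in range(n_ions)]
        self.initial_homes = list(self.homes)
        self.busy_until = [0] * n_ions
        # per-ion: list of (frame, new_home_sign) and (f_start, z_script)
        self.home_changes: list[list[tuple[int, int]]] = [[] for _ in range(n_ions)]
        self.segments: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n_ions)]

    def _free_in(self, reservoir, before_frame):
        cands = [
            i for i, h in enumerate(self.homes)
            if h == reservoir and self.busy_until[i] < before_frame
        ]
        if not cands:
            return None
        return min(cands, key=lambda i: self.busy_until[i])

    def schedule_crossing(self, f_end, direction, z_path):
        f_start = f_end - (self.m - 1)
        if f_start < 1:
            raise ConfigError(
                "crossing scheduled before the trajectory start; "
                "use a smaller dt or start events later"
            )
        source = -direction
        ion = self._free_in(source, f_start)
        if ion is None:
            # recruit from the far reservoir via a periodic wrap
            ion = self._free_in(-source, f_start - 1)
            if ion is None:
                raise ConfigError(
                    "no free ion to realise a crossing: event paths collide "
                    "in a single frame slot; use a smaller dt or lower rates"
                )
            self.wrap(ion, f_start - 1, source)
        self.segments[ion].append((f_start, z_path))
        self.home_changes[ion].append((f_end + 1, direction))
        self.homes[ion] = direction
        self.busy_until[ion] = f_end + 1
        return ion

    def wrap(self, ion, frame, new_home):
        self.home_changes[ion].append((frame, new_home))
        self.homes[ion] = new_home
        self.busy_until[ion] = max(self.busy_until[ion], frame)

    def wrap_idle(self, frame):
        """Wrap some idle ion at `frame` (exercises wrap rejection)."""
        for reservoir in (-1, 1):
            ion = self._free_in(reservoir, frame)
            if ion is not None:
                self.wrap(ion, frame, -reservoir)
                self.busy_until[ion] = frame + 1
                return ion
        return None

    def z_series(self, ion, rng, jitter_sd=0.4):
        z = np.empty(self.n_frames)
        z[:] = self.home_z[self.initial_homes[ion]]
        for f, h in sorted(self.home_changes[ion]):
            z[f:] = self.home_z[h]
        z += np.clip(rng.normal(0.0, jitter_sd, self.n_frames), -2.0, 2.0)
        for f_start, path in self.segments[ion]:
            z[f_start: f_start + len(path)] = path
        return z


def gen_channel_trajectory(config: ChannelSimConfig):
    """Generate a gated-channel trajectory plus its ground truth.

    Returns ``(Trajectory, ChannelGroundTruth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration / cfg.dt)) + 1
    times = np.arange(n_frames) * cfg.dt
    z_lo, z_hi = cfg.slab
    lx, ly, lz = cfg.box

    # reservoir home positions: far enough from the slab that a home-to-home
    # jump exceeds Lz/2 (so it reads as a periodic wrap), but inside the box
    span = z_hi - z_lo
    lo_bound = lz / 4 - span / 2
    hi_bound = lz / 2 - z_hi - 3.0
    if hi_bound <= max(lo_bound, 0):
        raise ConfigError(
            "box z edge too small relative to the slab to host reservoirs"
        )
    offset = 0.5 * (max(lo_bound, 4.0) + hi_bound)
    home_z = {-1: z_lo - offset, 1: z_hi + offset}

    # hidden gating state
    state_series, switch_times, switch_states = _simulate_two_state(
        rng, cfg.duration, cfg.k_open_to_closed, cfg.k_closed_to_open, times
    )
    intervals = _state_intervals(switch_times, switch_states, cfg.duration)

    # crossing events per species, Poisson within each state interval
    species_spec = [
        ("K", +1, cfg.n_cations),
        ("CL", -1, cfg.n_anions),
    ]
    approach = 4.0
    m = cfg.crossing_frames
    events: list[CrossingEvent] = []
    schedulers = {}
    raw_events = {}
    for sp, valence, n_ions in species_spec:
        if n_ions == 0:
            continue
        ev_times = []
        for t0, t1, st in intervals:
            rate = cfg.rate_open if st == 1 else cfg.rate_closed  # per µs
            lam = rate * (t1 - t0) / 1000.0
            n = rng.poisson(lam)
            ev_times.extend(rng.uniform(t0, t1, n))
        ev_times = np.sort(np.asarray(ev_times))
        # direction: with the field for cations (+1), against z for anions
        with_field = +1 if valence > 0 else -1
        dirs = np.where(rng.random(len(ev_times)) < cfg.p_drift,
                        with_field, -with_field)
        raw_events[sp] = (ev_times, dirs, valence, n_ions)

    up_path = np.linspace(z_lo - approach, z_hi + approach, m)
    for sp, (ev_times, dirs, valence, n_ions) in raw_events.items():
        sched = _IonScheduler(n_ions, n_frames, home_z, m)
        schedulers[sp] = sched
        for t, d in zip(ev_times, dirs):
            f_end = int(round(t / cfg.dt))
            f_end = min(max(f_end, m), n_frames - 2)
            path = up_path if d > 0 else up_path[::-1]
            ion_local = sched.schedule_crossing(f_end, int(d), path)
            events.append(
                CrossingEvent(
                    ion_index=ion_local,  # remapped to atom index below
                    species=sp,
                    valence=valence,
                    direction=int(d),
                    completion_time=float(times[f_end]),
                )
            )
        if cfg.scripted_wraps:
            for f in range(1000, n_frames - 1, 1000):
                sched.wrap_idle(f)

    # ---- water ----
    if cfg.water_coupled:
        means = np.where(state_series == 1, cfg.water_mean_open,
                         cfg.water_mean_closed).astype(float)
    else:
        frac_open = float(np.mean(state_series))
        const = frac_open * cfg.water_mean_open + (1 - frac_open) * cfg.water_mean_closed
        means = np.full(n_frames, const)
    peak = max(cfg.water_mean_open, cfg.water_mean_closed)
    n_pore_alloc = int(np.ceil(peak + 6 * np.sqrt(max(peak, 1.0)) + 5))
    water_counts = np.minimum(rng.poisson(means), n_pore_alloc)

    # ---- assemble topology ----
    atoms: list[Atom] = []
    serial = 1
    helix_coords = []
    n_helices, res_per_helix = 6, 17
    helix_r = cfg.pore_radius + 4.0
    for h in range(n_helices):
        theta = 2 * np.pi * h / n_helices
        zs = np.linspace(z_lo - 2.0, z_hi + 2.0, res_per_helix)
        for j, zc in enumerate(zs):
            wobble = 1.2 * np.cos(0.8 * j + theta)
            x = (helix_r + wobble) * np.cos(theta)
            y = (helix_r + wobble) * np.sin(theta)
            atoms.append(Atom(serial, "CA", "ALA", j + 1, chr(65 + h), "C", 0))
            helix_coords.append((x, y, zc))
            serial += 1
    helix_coords = np.asarray(helix_coords)

    index_map = {}
    for sp, valence, n_ions in species_spec:
        first = len(atoms)
        for i in range(n_ions):
            atoms.append(Atom(serial, sp, sp, i + 1, "I", sp.capitalize(), valence))
            serial += 1
        index_map[sp] = np.arange(first, first + n_ions)

    n_water_total = n_pore_alloc + cfg.n_bulk_waters
    water_first = len(atoms)
    for i in range(n_water_total):
        atoms.append(Atom(serial, "O", "HOH", i + 1, "W", "O", 0))
        serial += 1
    water_indices = np.arange(water_first, water_first + n_water_total)
    topology = Topology(atoms)

    # ---- coordinates ----
    coords = np.empty((n_frames, len(atoms), 3))
    coords[:, : len(helix_coords)] = helix_coords[None]

    for sp, (ev_times, dirs, valence, n_ions) in raw_events.items():
        sched = schedulers[sp]
        idx = index_map[sp]
        for i_local in range(n_ions):
            ai = idx[i_local]
            coords[:, ai, 2] = sched.z_series(i_local, rng)
            # xy: fixed reservoir spot, re-drawn after each scripted segment
            xy = rng.uniform(-0.35, 0.35, 2) * np.array([lx, ly])
            coords[:, ai, 0] = xy[0]
            coords[:, ai, 1] = xy[1]
            for f_start, path in sched.segments[i_local]:
                r = cfg.pore_radius * 0.5 * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                sl = slice(f_start, f_start + len(path))
                coords[sl, ai, 0] = r * np.cos(ang)
                coords[sl, ai, 1] = r * np.sin(ang)

    # waters: first `count` of the pore allocation sit inside the cylinder
    r_in = cfg.pore_radius * 0.85 * np.sqrt(rng.random((n_frames, n_pore_alloc)))
    ang_in = rng.uniform(0, 2 * np.pi, (n_frames, n_pore_alloc))
    z_in = rng.uniform(z_lo + 0.5, z_hi - 0.5, (n_frames, n_pore_alloc))
    in_pore = np.arange(n_pore_alloc)[None, :] < water_counts[:, None]
    park_z = lz / 2 - 6.0
    pore_block = np.stack(
        [r_in * np.cos(ang_in), r_in * np.sin(ang_in), z_in], axis=-1
    )
    parked = np.stack(
        [
            rng.uniform(-0.3 * lx, 0.3 * lx, (n_frames, n_pore_alloc)),
            rng.uniform(-0.3 * ly, 0.3 * ly, (n_frames, n_pore_alloc)),
            np.where(rng.random((n_frames, n_pore_alloc)) < 0.5, park_z, -park_z),
        ],
        axis=-1,
    )
    coords[:, water_indices[:n_pore_alloc]] = np.where(
        in_pore[..., None], pore_block, parked
    )
    bulk_xy = rng.uniform(-0.4, 0.4, (cfg.n_bulk_waters, 2)) * np.array([lx, ly])
    bulk_z = np.where(rng.random(cfg.n_bulk_waters) < 0.5, park_z, -park_z)
    coords[:, water_indices[n_pore_alloc:], :2] = bulk_xy[None]
    coords[:, water_indices[n_pore_alloc:], 2] = bulk_z[None]

    # remap event ion indices from species-local to topology indices
    events = [
        CrossingEvent(
            ion_index=int(index_map[e.species][e.ion_index]),
            species=e.species,
            valence=e.valence,
            direction=e.direction,
            completion_time=e.completion_time,
        )
        for e in events
    ]
    events.sort(key=lambda e: e.completion_time)

    boxes = np.tile(np.asarray(cfg.box, dtype=float), (n_frames, 1))
    traj = Trajectory(topology, times, coords, boxes)
    truth = ChannelGroundTruth(
        events=events,
        state_series=np.asarray(state_series, dtype=int),
        water_counts=water_counts.astype(int),
        cation_indices=index_map.get("K", np.empty(0, int)),
        anion_indices=index_map.get("CL", np.empty(0, int)),
        water_indices=water_indices,
    )
    return traj, truth


def poisson_events(
    rate_per_us: float,
    duration_ns: float,
    seed: int | np.random.Generator = 0,
    species: str = "K",
    valence: int = +1,
    direction: int = +1,
) -> list[CrossingEvent]:
    """Homogeneous Poisson crossing events (no trajectory), for estimator
    validation against closed-form Poisson statistics."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate_per_us * duration_ns / 1000.0)
    ts = np.sort(rng.uniform(0.0, duration_ns, n))
    return [
        CrossingEvent(ion_index=0, species=species, valence=valence,
                      direction=direction, completion_time=float(t))
        for t in ts
    ]


# ---------------------------------------------------------------------------
# Ligase-like system
# ---------------------------------------------------------------------------

#: (resid -> (resname, side-chain donor atom names)) for the mimic; every
#: other residue is ALA with backbone only.
_SPECIAL_RESIDUES = {
    17: ("LYS", ("NZ",)),
    18: ("HIS", ("ND1",)),
    20: ("CYS", ("SG",)),
    28: ("GLU", ("OE1", "OE2")),
    29: ("ASP", ("OD1", "OD2")),
    34: ("ASP", ("OD1", "OD2")),
    43: ("ASP", ("OD1", "OD2")),
    55: ("ASP", ("OD1", "OD2")),
    57: ("CYS", ("SG",)),
    61: ("ARG", ("NH1",)),
    65: ("HIS", ("ND1",)),
}

#: Default Zn coordination: two sites tethering the loop's ends.
_DEFAULT_ZN_SITES = [
    [(18, "HIS", "ND1"), (20, "CYS", "SG"), (34, "ASP", "OD1")],
    [(28, "GLU", "OE1"), (57, "CYS", "SG"), (65, "HIS", "ND1")],
]

COORDINATED_DISTANCE = 2.1  # Å, metal–donor when ligated
RELEASED_DISTANCE = 4.5  # Å, metal–donor when parked outside the sphere
BRIDGE_ON_DISTANCE = 3.0  # Å, N–O when a scripted salt bridge is formed
BRIDGE_OFF_DISTANCE = 6.0  # Å, N–O otherwise


@dataclass
class LigaseSimConfig:
    """Study conditions for the metal-cored flexible-protein generator."""

    n_residues: int = 87
    core_ranges: tuple = ((18, 34), (57, 65))
    loop_range: tuple[int, int] = (35, 56)
    sigma_core: float = 0.7  # Å, i.i.d. per-atom displacement in the core
    sigma_loop: float = 2.5  # Å, chain-correlated per-residue displacement
    sigma_tail: float = 3.0  # Å, i.i.d. displacement of the termini
    zn_sites: list = field(default_factory=lambda: [list(s) for s in _DEFAULT_ZN_SITES])
    substitution_script: tuple | None = None  # (frame, lost Ligand, gained Ligand)
    salt_bridge_script: list = field(
        default_factory=lambda: list(_DEFAULT_SALT_BRIDGES)
    )  # (basic resid, acidic resid, occupancy)
    n_frames: int = 1000
    dt: float = 0.55  # ns per frame (1000 frames = 550 ns)
    box: tuple[float, float, float] = (96.0, 96.0, 96.0)
    seed: int = 0

    def __post_init__(self):
        ranges = list(self.core_ranges) + [self.loop_range]
        covered: set[int] = set()
        for start, end in ranges:
            if not (1 <= start <= end <= self.n_residues):
                raise ConfigError(
                    f"range {start}-{end} outside 1..{self.n_residues}"
                )
            block = set(range(start, end + 1))
            if covered & block:
                raise ConfigError("core/loop residue ranges overlap")
            covered |= block
        for s in ("sigma_core", "sigma_loop", "sigma_tail"):
            if getattr(self, s) < 0:
                raise ConfigError(f"{s} must be ≥ 0")
        if self.substitution_script is not None:
            frame = self.substitution_script[0]
            if not 0 <= frame < self.n_frames:
                raise ConfigError(
                    f"substitution frame {frame} beyond n_frames {self.n_frames}"
                )
        for b, a, occ in self.salt_bridge_script:
            if not 0 <= occ <= 1:
                raise ConfigError(
                    f"salt-bridge occupancy {occ} for ({b},{a}) not in [0, 1]"
                )
        if self.n_frames < 1 or self.dt <= 0:
            raise ConfigError("n_frames must be ≥ 1 and dt > 0")


@dataclass
class LigaseGroundTruth:
    zn_indices: np.ndarray  # topology indices of the Zn atoms
    site_ligands: list  # per site, list of Ligand tuples at t=0
    substitution: tuple | None  # (frame, lost, gained)
    salt_bridges: list  # (basic resid, acidic resid, occupancy, frames array)


def _backbone_curve(n_residues: int):
    """Smooth self-avoiding CA trace with ~3.8 Å steps, plus N/C offsets."""
    i = np.arange(n_residues)
    theta = 0.25 * i
    radius = 14.0
    ca = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), 1.5 * i], axis=1
    )
    ca -= ca.mean(axis=0)
    tangent = np.gradient(ca, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    radial = ca - np.array([0.0, 0.0, 1.0]) * ca[:, 2:3]
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radial = radial / norms
    n_pos = ca - 1.2 * tangent + 0.4 * radial
    c_pos = ca + 1.2 * tangent + 0.4 * radial
    return ca, n_pos, c_pos, radial


def gen_ligase_trajectory(config: LigaseSimConfig):
    """Generate the flexible-protein mimic plus its ground truth.

    Returns ``(Trajectory, LigaseGroundTruth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nres = cfg.n_residues
    ca, n_pos, c_pos, radial = _backbone_curve(nres)

    atoms: list[Atom] = []
    ref = []
    serial = 1
    atom_lookup: dict[tuple[int, str], int] = {}
    residue_of_atom: list[int] = []
    for r in range(1, nres + 1):
        resname, extras = _SPECIAL_RESIDUES.get(r, ("ALA", ()))
        for name, pos in (("N", n_pos[r - 1]), ("CA", ca[r - 1]), ("C", c_pos[r - 1])):
            atoms.append(Atom(serial, name, resname, r, "A", name[0], 0))
            ref.append(pos)
            atom_lookup[(r, name)] = len(atoms) - 1
            residue_of_atom.append(r)
            serial += 1
        for k, name in enumerate(extras):
            pos = ca[r - 1] + (2.5 + 1.1 * k) * radial[r - 1]
            atoms.append(Atom(serial, name, resname, r, "A", name[0], 0))
            ref.append(pos)
            atom_lookup[(r, name)] = len(atoms) - 1
            residue_of_atom.append(r)
            serial += 1

    # Zn particles at the centroid of their ligands' CA positions
    zn_refs = []
    zn_indices = []
    for site in cfg.zn_sites:
        cas = np.array([ca[rid - 1] for rid, _, _ in site])
        center = cas.mean(axis=0) + np.array([0.0, 0.0, 0.0])
        zn_refs.append(center)
        atoms.append(Atom(serial, "ZN", "ZN", 200 + len(zn_indices), "Z", "Zn", +2))
        ref.append(center)
        zn_indices.append(len(atoms) - 1)
        residue_of_atom.append(0)
        serial += 1
    topology = Topology(atoms)
    ref = np.asarray(ref)
    n_atoms = len(atoms)

    # region membership per atom (0 tail, 1 core, 2 loop)
    region = np.zeros(n_atoms, dtype=int)
    res_arr = np.asarray(residue_of_atom)
    for start, end in cfg.core_ranges:
        region[(res_arr >= start) & (res_arr <= end)] = 1
    l0, l1 = cfg.loop_range
    region[(res_arr >= l0) & (res_arr <= l1)] = 2
    region[np.asarray(zn_indices)] = 1  # jitters rigidly with the core sites

    # which atoms are fully scripted (exempt from region noise)
    scripted = np.zeros(n_atoms, dtype=bool)
    scripted[zn_indices] = True

    # tetrahedral-ish unit directions for donor placement around each Zn
    site_dirs = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1], [0, 1.2, -0.6]],
        dtype=float,
    )
    site_dirs /= np.linalg.norm(site_dirs, axis=1, keepdims=True)

    sub = cfg.substitution_script
    # map each scripted donor to (zn site, direction index, distance schedule)
    donor_plan = []  # (atom_idx, partner_idx|None, site, dir_idx, dist array)
    nf = cfg.n_frames
    for s, site in enumerate(cfg.zn_sites):
        for k, lig in enumerate(site):
            rid, rname, aname = lig
            ai = atom_lookup[(rid, aname)]
            dist = np.full(nf, COORDINATED_DISTANCE)
            if sub is not None and tuple(sub[1]) == (rid, rname, aname):
                dist[sub[0]:] = RELEASED_DISTANCE
            donor_plan.append((ai, s, k, dist))
            scripted[ai] = True
    if sub is not None:
        frame, lost, gained = sub
        rid, rname, aname = gained
        ai = atom_lookup[(rid, aname)]
        # gained ligand belongs to the same site as the lost one
        site_of_lost = next(
            s for s, site in enumerate(cfg.zn_sites)
            if tuple(lost) in {tuple(l) for l in site}
        )
        dist = np.full(nf, RELEASED_DISTANCE)
        dist[frame:] = COORDINATED_DISTANCE
        donor_plan.append((ai, site_of_lost, 3, dist))
        scripted[ai] = True
    else:
        # park the spare donor (D29) near the second site, outside the sphere
        if (29, "OD1") in atom_lookup and len(cfg.zn_sites) > 1:
            donor_plan.append(
                (atom_lookup[(29, "OD1")], 1, 3, np.full(nf, RELEASED_DISTANCE))
            )
            scripted[atom_lookup[(29, "OD1")]] = True

    # carboxylate partner atoms (OD2/OE2) ride 1.1 Å further from the metal
    partner_of = {}
    for ai, s, k, dist in donor_plan:
        rid = int(res_arr[ai])
        name = str(topology.names[ai])
        partner = {"OD1": "OD2", "OE1": "OE2"}.get(name)
        if partner and (rid, partner) in atom_lookup:
            pi = atom_lookup[(rid, partner)]
            partner_of[ai] = pi
            scripted[pi] = True

    # salt-bridge scripting: exact occupied-frame sets
    bridges = []
    for b_rid, a_rid, occ in cfg.salt_bridge_script:
        n_on = int(round(occ * nf))
        on_frames = np.sort(rng.choice(nf, size=n_on, replace=False))
        on_mask = np.zeros(nf, dtype=bool)
        on_mask[on_frames] = True
        b_name = "NZ" if (b_rid, "NZ") in atom_lookup else "NH1"
        bi = atom_lookup[(b_rid, b_name)]
        ai1 = atom_lookup[(a_rid, "OD1")]
        ai2 = atom_lookup.get((a_rid, "OD2"))
        scripted[bi] = True
        if ai2 is not None:
            scripted[ai2] = True
        bridges.append((bi, ai1, ai2, on_mask, b_rid, a_rid, n_on / nf, on_frames))

    # ---- per-frame coordinates ----
    coords = np.tile(ref[None], (nf, 1, 1))
    noise = np.zeros((nf, n_atoms, 3))
    core_atoms = np.flatnonzero((region == 1) & ~scripted)
    if cfg.sigma_core > 0 and len(core_atoms):
        noise[:, core_atoms] = rng.normal(0, cfg.sigma_core,
                                          (nf, len(core_atoms), 3))
    tail_atoms = np.flatnonzero((region == 0) & ~scripted)
    if cfg.sigma_tail > 0 and len(tail_atoms):
        noise[:, tail_atoms] = rng.normal(0, cfg.sigma_tail,
                                          (nf, len(tail_atoms), 3))
    # loop: per-residue displacement, smoothed along the chain so nearby
    # residues move together (correlation length ≈ 2 residues)
    loop_res = np.arange(l0, l1 + 1)
    if cfg.sigma_loop > 0:
        g = rng.normal(0, 1.0, (nf, len(loop_res) + 8, 3))
        g = gaussian_filter1d(g, sigma=2.0, axis=1, mode="wrap")
        impulse = np.zeros(101)
        impulse[50] = 1.0
        kernel = gaussian_filter1d(impulse, sigma=2.0)
        g *= cfg.sigma_loop / np.sqrt(np.sum(kernel**2))
        g = g[:, 4:4 + len(loop_res)]
        for j, rid in enumerate(loop_res):
            sel = np.flatnonzero((res_arr == rid) & ~scripted)
            noise[:, sel] = g[:, [j]]
    coords += noise

    # rigid per-frame jitter of each Zn site (metal + donors move together)
    site_jitter = rng.normal(0, cfg.sigma_core, (nf, len(cfg.zn_sites), 3))
    for s, zi in enumerate(zn_indices):
        coords[:, zi] = ref[zi] + site_jitter[:, s]
    for ai, s, k, dist in donor_plan:
        direction = site_dirs[k % len(site_dirs)]
        coords[:, ai] = (
            ref[zn_indices[s]] + site_jitter[:, s] + dist[:, None] * direction
        )
        if ai in partner_of:
            coords[:, partner_of[ai]] = coords[:, ai] + 1.1 * direction

    for bi, ai1, ai2, on_mask, b_rid, a_rid, occ, _ in bridges:
        u = coords[:, bi] - coords[:, ai1]
        norm = np.linalg.norm(u, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        u = u / norm
        d = np.where(on_mask, BRIDGE_ON_DISTANCE, BRIDGE_OFF_DISTANCE)
        coords[:, bi] = coords[:, ai1] + d[:, None] * u
        if ai2 is not None:
            coords[:, ai2] = coords[:, ai1] - 1.1 * u

    times = np.arange(nf) * cfg.dt
    boxes = np.tile(np.asarray(cfg.box, dtype=float), (nf, 1))
    traj = Trajectory(topology, times, coords, boxes)
    truth = LigaseGroundTruth(
        zn_indices=np.asarray(zn_indices),
        site_ligands=[[tuple(l) for l in site] for site in cfg.zn_sites],
        substitution=(
            None if sub is None else (int(sub[0]), tuple(sub[1]), tuple(sub[2]))
        ),
        salt_bridges=[
            (b_rid, a_rid, occ, on_frames)
            for _, _, _, _, b_rid, a_rid, occ, on_frames in bridges
        ],
    )
    return traj, truth
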
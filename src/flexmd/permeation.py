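"""Ion permeation analysis: crossing detection, flux series, conductance.

The current through the channel is estimated by counting complete ion
traversals.  An ion crosses when it moves from the reservoir below the
channel slab to the reservoir above it (direction +1) or vice versa (−1)
without passing through the periodic z boundary.  The single-channel
conductance is the transported charge per unit time divided by the applied
voltage, G = Q / (T · V), reported in pS.

Because open and constricted periods of a flexible channel are long
compared with typical trajectory lengths, crossing events are strongly
autocorrelated; uncertainty is therefore estimated with a moving-block
bootstrap over contiguous time blocks rather than an i.i.d. event
bootstrap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SelectionError
from .model import ChannelDefinition, Trajectory

logger = logging.getLogger(__name__)

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

# G[pS] = (sum valence*direction) * q_e / (T[ns]*1e-9 s) / (V[mV]*1e-3 V) * 1e12
_PS_FACTOR = ELEMENTARY_CHARGE * 1e24


@dataclass(frozen=True)
class CrossingEvent:
    """One complete channel traversal."""

    ion_index: int  # atom index in the topology
    species: str  # residue name, e.g. "K" or "CL"
    valence: int  # elementary charges
    direction: int  # +1: z_lo -> z_hi, -1: z_hi -> z_lo
    completion_time: float  # ns, frame at which the ion reaches the far side

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ConfigError(f"direction must be ±1, got {self.direction}")


@dataclass
class FluxSeries:
    """Cumulative crossings per species on a common time grid."""

    grid: np.ndarray  # ns
    total: dict[str, np.ndarray]  # direction-summed counts
    net: dict[str, np.ndarray]  # signed counts


@dataclass
class ConductanceEstimate:
    """Point estimate of single-channel conductance with bootstrap spread."""

    conductance: float  # pS
    bootstrap_sd: float  # pS
    n_boot: int
    block_length: float  # ns
    voltage: float  # mV
    total_time: float  # ns
    n_events: int
    ci_low: float = float("nan")  # 95% percentile interval, pS
    ci_high: float = float("nan")
    replicates: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def as_summary(self) -> dict:
        return {
            "conductance_pS": self.conductance,
            "bootstrap_sd_pS": self.bootstrap_sd,
            "ci95_low_pS": self.ci_low,
            "ci95_high_pS": self.ci_high,
            "n_boot": self.n_boot,
            "block_length_ns": self.block_length,
            "voltage_mV": self.voltage,
            "total_time_ns": self.total_time,
            "n_events": self.n_events,
        }


def _region(z: float, z_lo: float, z_hi: float) -> int:
    """-1 below the slab, 0 inside, +1 above."""
    if z < z_lo:
        return -1
    if z > z_hi:
        return 1
    return 0


def detect_crossings(
    traj: Trajectory,
    chan: ChannelDefinition,
    ion_indices,
) -> list[CrossingEvent]:
    """Detect complete channel traversals for the selected ions.

    Per-ion three-region state machine on z (below / inside / above the
    slab).  An event is emitted when an ion reaches the reservoir opposite
    the one it last occupied.  A single-step jump whose raw z displacement
    exceeds Lz/2 is a periodic wrap through the box edge — the state
    resets and no event is emitted.  A below→above jump in one step with
    |Δz| < Lz/2 is a genuine fast traversal and counts (logged, since the
    frame spacing is then too coarse to resolve the pore passage).

    With ``chan.pore_radius`` set, frames spent inside the slab must stay
    within that radial distance of the pore axis or the traversal is
    discarded (radial gate).
    """
    if traj.n_frames < 2:
        raise ConfigError("crossing detection requires at least 2 frames")
    ion_indices = np.atleast_1d(np.asarray(ion_indices, dtype=int))
    top = traj.topology
    bad = [i for i in ion_indices if top.valences[i] == 0]
    if bad:
        raise SelectionError(
            f"ions {bad} have valence 0; including them would corrupt the "
            "current estimate (fix the species table or the selection)"
        )

    z_lo, z_hi = chan.z_lo, chan.z_hi
    use_gate = chan.pore_radius is not None
    events: list[CrossingEvent] = []
    times = traj.times
    lz_half = traj.boxes[:, 2] / 2.0

    for ion in ion_indices:
        z = traj.coordinates[:, ion, 2]
        if use_gate:
            dx = traj.coordinates[:, ion, 0] - chan.axis_xy[0]
            dy = traj.coordinates[:, ion, 1] - chan.axis_xy[1]
            r2 = dx * dx + dy * dy
            gate_ok = r2 <= chan.pore_radius**2
        origin = _region(z[0], z_lo, z_hi) or None
        gate_violated = False
        for i in range(1, traj.n_frames):
            dz = z[i] - z[i - 1]
            reg = _region(z[i], z_lo, z_hi)
            if abs(dz) > lz_half[i]:
                # periodic wrap through the box edge: reset, never an event
                origin = reg or None
                gate_violated = False
                continue
            if reg == 0:
                if use_gate and not gate_ok[i]:
                    gate_violated = True
                continue
            if origin is None:
                origin = reg
                gate_violated = False
                continue
            if reg != origin:
                if abs(dz) > (z_hi - z_lo):
                    logger.info(
                        "ion %d traversed the slab in a single step at "
                        "t=%.4g ns; frame spacing is coarse", ion, times[i],
                    )
                if not gate_violated:
                    events.append(
                        CrossingEvent(
                            ion_index=int(ion),
                            species=str(top.residue_names[ion]),
                            valence=int(top.valences[ion]),
                            direction=int(reg),
                            completion_time=float(times[i]),
                        )
                    )
                origin = reg
            gate_violated = False
    events.sort(key=lambda e: e.completion_time)
    return events


def cumulative_flux(events: list[CrossingEvent], grid) -> FluxSeries:
    """Step functions of cumulative total and net crossings per species."""
    grid = np.asarray(grid, dtype=float)
    species = sorted({e.species for e in events})
    total = {}
    net = {}
    for sp in species:
        times = np.array([e.completion_time for e in events if e.species == sp])
        signs = np.array([e.direction for e in events if e.species == sp])
        order = np.argsort(times, kind="stable")
        times, signs = times[order], signs[order]
        idx = np.searchsorted(times, grid, side="right")
        total[sp] = idx.astype(int)
        csum = np.concatenate([[0], np.cumsum(signs)])
        net[sp] = csum[idx]
    return FluxSeries(grid=grid, total=total, net=net)


def transported_charge(events) -> int:
    """Net transported charge in elementary-charge units.

    With the field along +z, a cation crossing +1 and an anion crossing −1
    both contribute +1: charge moves with the field in both cases.
    """
    return int(sum(e.valence * e.direction for e in events))


def estimate_conductance(
    events,
    chan: ChannelDefinition,
    total_time: float,
) -> float:
    """Single-channel conductance in pS by ion counting.

    G = Q / (T · V) with Q the net transported charge.  A negative value
    (net flux against the field) is returned as-is with a warning.
    """
    if total_time <= 0:
        raise ConfigError("total_time must be positive")
    if chan.voltage == 0:
        raise ConfigError("voltage must be nonzero to estimate conductance")
    n_q = transported_charge(events)
    g = n_q * _PS_FACTOR / (total_time * chan.voltage)
    if g < 0:
        logger.warning("negative conductance %.3g pS: net flux against the field", g)
    return g


def _blocks(events, total_time: float, block_length: float):
    """Cut [0, total_time] into contiguous blocks.

    Returns (charges, durations): per-block transported charge (elementary
    charges) and block length (ns).  The final block may be shorter; its
    events and its duration travel together.
    """
    if block_length <= 0:
        raise ConfigError("block_length must be positive")
    if block_length > total_time:
        raise ConfigError(
            f"block_length ({block_length} ns) exceeds total_time "
            f"({total_time} ns)"
        )
    edges = np.arange(0.0, total_time, block_length)
    durations = np.minimum(block_length, total_time - edges)
    charges = np.zeros(len(edges))
    for e in events:
        b = min(int(e.completion_time // block_length), len(edges) - 1)
        charges[b] += e.valence * e.direction
    return charges, durations


def bootstrap_conductance(
    events,
    chan: ChannelDefinition,
    total_time: float,
    block_length: float = 500.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    pooled: list[tuple[list, float]] | None = None,
) -> ConductanceEstimate:
    """Moving-block bootstrap of the ion-counting conductance.

    The record [0, total_time] is cut into contiguous blocks of
    `block_length` ns (the trailing remainder forms a shorter block).  Each
    replicate resamples blocks with replacement until the resampled
    duration reaches the original total, then recomputes G on the
    concatenated record.  The point estimate is the full-record G; the
    spread over replicates estimates its sampling uncertainty under the
    long open/constricted periods that make events autocorrelated.

    `pooled` adds further (events, total_time) records whose blocks join
    the resampling pool, as when several trajectories of the same system
    are combined into one conductance estimate.
    """
    if n_boot < 2:
        raise ConfigError("n_boot must be ≥ 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    records = [(list(events), float(total_time))]
    if pooled:
        records += [(list(ev), float(tt)) for ev, tt in pooled]

    charges_l, durations_l = [], []
    for ev, tt in records:
        c, d = _blocks(ev, tt, block_length)
        charges_l.append(c)
        durations_l.append(d)
    charges = np.concatenate(charges_l)
    durations = np.concatenate(durations_l)
    if len(charges) == 0:
        raise ConfigError("record produced zero blocks")

    grand_time = float(sum(tt for _, tt in records))
    all_events = [e for ev, _ in records for e in ev]
    point = estimate_conductance(all_events, chan, grand_time)

    n_blocks = len(charges)
    # enough draws to always reach grand_time, even if short blocks repeat
    max_draws = int(np.ceil(grand_time / durations.min())) + 1
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_blocks, size=max_draws)
        cum = np.cumsum(durations[idx])
        stop = int(np.searchsorted(cum, grand_time, side="left"))
        stop = min(stop, max_draws - 1)
        q = charges[idx[: stop + 1]].sum()
        reps[b] = q * _PS_FACTOR / (cum[stop] * chan.voltage)

    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ConductanceEstimate(
        conductance=point,
        bootstrap_sd=float(np.std(reps, ddof=1)),
        n_boot=n_boot,
        block_length=block_length,
        voltage=chan.voltage,
        total_time=grand_time,
        n_events=len(all_events),
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=reps,
    )
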
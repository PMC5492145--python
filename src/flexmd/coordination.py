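"""Metal coordination spheres, ligand substitutions and salt bridges.

In a protein whose core is organised by metal ions rather than hydrophobic
packing, the identity of the coordinating donor atoms is the structural
observable: a mutation that removes one ligand can be rescued by a
neighbouring hydrophilic residue taking its place, and core rearrangements
show up as new salt bridges.  All distances here use the minimum-image
convention in orthorhombic boxes, and all cutoff comparisons are inclusive
(≤).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SelectionError
from .model import Trajectory, minimum_image_distance

logger = logging.getLogger(__name__)

#: Side-chain/backbone donor atom names considered for metal coordination:
#: carboxylate O, thiolate S, imidazole N and backbone carbonyl O.
DEFAULT_DONOR_NAMES = frozenset(
    {"OD1", "OD2", "OE1", "OE2", "SG", "ND1", "NE2", "O"}
)

#: Atom names on basic (Lys/Arg) and acidic (Asp/Glu) side chains used for
#: salt-bridge geometry.
BASIC_N_NAMES = frozenset({"NZ", "NH1", "NH2", "NE"})
ACIDIC_O_NAMES = frozenset({"OD1", "OD2", "OE1", "OE2"})
BASIC_RESNAMES = frozenset({"LYS", "ARG"})
ACIDIC_RESNAMES = frozenset({"ASP", "GLU"})

#: A coordination ligand: (residue_id, residue_name, atom_name).
Ligand = tuple


@dataclass
class CoordinationRecord:
    frame: int
    metal_index: int  # atom index of the metal
    ligands: frozenset  # of (residue_id, residue_name, atom_name)


@dataclass
class SubstitutionEvent:
    """A stable change in a metal's coordination sphere."""

    metal_index: int
    lost: frozenset  # ligands that left
    gained: frozenset  # ligands that entered
    frame: int  # first frame of the new, stable composition


@dataclass
class SaltBridgeRecord:
    basic_residue: tuple  # (residue_id, residue_name)
    acidic_residue: tuple
    distances: np.ndarray  # per-frame minimum N–O distance, Å
    occupancy: float  # fraction of frames with distance ≤ cutoff
    cutoff: float


def metal_coordination(
    traj: Trajectory,
    metal_indices,
    donor_names=DEFAULT_DONOR_NAMES,
    cutoff: float = 2.8,
) -> list[CoordinationRecord]:
    """Per-frame coordination sphere of each metal.

    Donor atoms (by name) within `cutoff` Å of the metal under minimum
    image are reported; the boundary is inclusive.  The 2.8 Å default is a
    generous upper bound for Zn–O/N/S first-shell contacts.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    metal_indices = np.atleast_1d(np.asarray(metal_indices, dtype=int))
    top = traj.topology
    for m in metal_indices:
        if not 0 <= m < top.n_atoms:
            raise SelectionError(f"unknown metal atom index {m}")
    donor_idx = top.select(atom_names=set(donor_names))
    donor_idx = donor_idx[~np.isin(donor_idx, metal_indices)]
    donor_ligands = [
        (int(top.residue_ids[i]), str(top.residue_names[i]), str(top.names[i]))
        for i in donor_idx
    ]
    records: list[CoordinationRecord] = []
    for m in metal_indices:
        d = minimum_image_distance(
            traj.coordinates[:, donor_idx],
            traj.coordinates[:, [m]],
            traj.boxes[:, None, :],
        )  # (n_frames, n_donors)
        within = d <= cutoff
        for f in range(traj.n_frames):
            records.append(
                CoordinationRecord(
                    frame=f,
                    metal_index=int(m),
                    ligands=frozenset(
                        donor_ligands[j] for j in np.flatnonzero(within[f])
                    ),
                )
            )
    return records


def detect_substitutions(
    records: list[CoordinationRecord], persistence: int = 25
) -> list[SubstitutionEvent]:
    """Call ligand-substitution events from a coordination time series.

    The per-metal ligand-set series is compressed into runs of identical
    composition; runs shorter than `persistence` frames are flickers and
    are only logged.  An event is emitted between consecutive stable runs
    whenever at least one ligand left *and* a different one entered.
    """
    if persistence < 1:
        raise ConfigError("persistence must be ≥ 1")
    by_metal: dict[int, list[CoordinationRecord]] = {}
    for r in records:
        by_metal.setdefault(r.metal_index, []).append(r)
    events: list[SubstitutionEvent] = []
    for metal, recs in by_metal.items():
        recs = sorted(recs, key=lambda r: r.frame)
        runs: list[tuple[frozenset, int, int]] = []  # (ligands, start, length)
        for r in recs:
            if runs and runs[-1][0] == r.ligands:
                lig, start, length = runs[-1]
                runs[-1] = (lig, start, length + 1)
            else:
                runs.append((r.ligands, r.frame, 1))
        stable = [run for run in runs if run[2] >= persistence]
        n_flicker = len(runs) - len(stable)
        if n_flicker:
            logger.debug(
                "metal %d: %d sub-persistence composition runs ignored",
                metal, n_flicker,
            )
        for (prev, _, _), (cur, start, _) in zip(stable, stable[1:]):
            lost = prev - cur
            gained = cur - prev
            if lost and gained:
                events.append(
                    SubstitutionEvent(
                        metal_index=metal,
                        lost=lost,
                        gained=gained,
                        frame=start,
                    )
                )
    events.sort(key=lambda e: (e.frame, e.metal_index))
    return events


def pair_distance_series(traj: Trajectory, index_a: int, index_b: int) -> np.ndarray:
    """Minimum-image distance between two atoms, per frame (Å)."""
    if index_a == index_b:
        raise SelectionError(f"atom index {index_a} given twice")
    top = traj.topology
    for i in (index_a, index_b):
        if not 0 <= i < top.n_atoms:
            raise SelectionError(f"unknown atom index {i}")
    return minimum_image_distance(
        traj.coordinates[:, index_a],
        traj.coordinates[:, index_b],
        traj.boxes,
    )


def detect_salt_bridges(
    traj: Trajectory,
    cutoff: float = 4.0,
    occupancy_min: float = 0.5,
) -> list[SaltBridgeRecord]:
    """Salt bridges between basic (Lys/Arg) and acidic (Asp/Glu) residues.

    For every basic–acidic residue pair, the per-frame distance is the
    minimum over side-chain N···O atom pairs under minimum image.  Pairs
    bridged (distance ≤ cutoff, inclusive) in at least `occupancy_min` of
    frames are reported with their occupancy.
    """
    if not 0 <= occupancy_min <= 1:
        raise ConfigError("occupancy_min must be in [0, 1]")
    top = traj.topology
    basic_idx = top.select(residue_names=set(BASIC_RESNAMES),
                           atom_names=set(BASIC_N_NAMES))
    acidic_idx = top.select(residue_names=set(ACIDIC_RESNAMES),
                            atom_names=set(ACIDIC_O_NAMES))
    basic_res: dict[tuple, list[int]] = {}
    for i in basic_idx:
        basic_res.setdefault(
            (int(top.residue_ids[i]), str(top.residue_names[i])), []
        ).append(int(i))
    acidic_res: dict[tuple, list[int]] = {}
    for i in acidic_idx:
        acidic_res.setdefault(
            (int(top.residue_ids[i]), str(top.residue_names[i])), []
        ).append(int(i))

    out: list[SaltBridgeRecord] = []
    for bres, b_atoms in sorted(basic_res.items()):
        for ares, a_atoms in sorted(acidic_res.items()):
            d = minimum_image_distance(
                traj.coordinates[:, b_atoms, None, :],
                traj.coordinates[:, None, a_atoms, :],
                traj.boxes[:, None, None, :],
            )  # (n_frames, n_b, n_a)
            dmin = d.min(axis=(1, 2))
            occ = float(np.mean(dmin <= cutoff))
            if occ >= occupancy_min:
                out.append(
                    SaltBridgeRecord(
                        basic_residue=bres,
                        acidic_residue=ares,
                        distances=dmin,
                        occupancy=occ,
                        cutoff=cutoff,
                    )
                )
    return out
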
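"""Backbone flexibility via least-squares superposition and region RMSD.

A flexible protein shows very different RMSD depending on where you look:
a metal-tethered core stays within a couple of Å of the initial structure
while a catalytic loop wanders much further.  This module quantifies that
contrast by superposing each region onto the reference frame and recording
the minimised RMSD per frame.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SelectionError
from .model import Topology, Trajectory, minimum_image

#: Backbone atom names used for RMSD; carbonyl O excluded by default.
DEFAULT_BACKBONE = frozenset({"N", "CA", "C"})


@dataclass
class RegionSelection:
    """A named set of residue ranges restricted to backbone atoms."""

    name: str
    residue_ranges: list[tuple[int, int]]  # inclusive ranges
    backbone_atoms: frozenset = DEFAULT_BACKBONE

    def resolve(self, topology: Topology) -> np.ndarray:
        """Atom indices in file order; raises if the selection is empty."""
        resids: list[int] = []
        for start, end in self.residue_ranges:
            resids.extend(range(start, end + 1))
        idx = topology.select(residue_ids=resids, atom_names=set(self.backbone_atoms))
        if len(idx) == 0:
            raise SelectionError(
                f"region {self.name!r} (residues {self.residue_ranges}, atoms "
                f"{sorted(self.backbone_atoms)}) selects no atoms"
            )
        return idx


@dataclass
class RmsdSeries:
    region: str
    times: np.ndarray  # ns
    rmsd: np.ndarray  # Å
    reference_frame: int


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns ``(rotation, translation, rmsd)`` where
    ``rotation @ x + translation`` maps mobile points onto the reference.
    The rotation is always proper (det = +1); reflections are excluded.
    Point sets must match in length and contain at least 3 points; a
    unique rotation additionally requires the points not to be collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError(
            f"point counts differ: mobile {mobile.shape} vs reference "
            f"{reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise SelectionError("superposition needs ≥ 3 points of shape (n, 3)")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    # residual-based RMSD: scipy's rssd loses precision near zero residual
    res = mob_c @ matrix.T - ref_c
    rmsd = float(np.sqrt(np.mean(np.sum(res * res, axis=1))))
    translation = ref_mean - matrix @ mob_mean
    return matrix, translation, rmsd


def region_rmsd(
    traj: Trajectory,
    region: RegionSelection,
    reference_frame: int = 0,
    fit_region: RegionSelection | None = None,
) -> RmsdSeries:
    """Per-frame minimised backbone RMSD of a region vs a reference frame.

    By default the fit uses the region's own atoms (each region is
    superposed on itself, which is what per-region flexibility plots
    report).  Pass `fit_region` to superpose on one region — typically the
    rigid core — while measuring another.
    """
    measure_idx = region.resolve(traj.topology)
    if len(measure_idx) < 3:
        raise SelectionError(
            f"region {region.name!r} resolves to {len(measure_idx)} atoms; "
            "superposition needs at least 3"
        )
    if not 0 <= reference_frame < traj.n_frames:
        raise SelectionError(f"reference frame {reference_frame} out of range")
    fit_idx = measure_idx if fit_region is None else fit_region.resolve(traj.topology)

    ref_fit = traj.coordinates[reference_frame, fit_idx]
    ref_measure = traj.coordinates[reference_frame, measure_idx]
    out = np.empty(traj.n_frames)
    same = fit_region is None
    for i in range(traj.n_frames):
        if same:
            _, _, out[i] = superpose(traj.coordinates[i, measure_idx], ref_fit)
        else:
            rot, trans, _ = superpose(traj.coordinates[i, fit_idx], ref_fit)
            moved = traj.coordinates[i, measure_idx] @ rot.T + trans
            out[i] = float(np.sqrt(np.mean(np.sum((moved - ref_measure) ** 2, axis=1))))
    return RmsdSeries(
        region=region.name,
        times=traj.times.copy(),
        rmsd=out,
        reference_frame=reference_frame,
    )


def unwrap_chain(coordinates: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a bonded chain whole across periodic boundaries.

    Walks the atom sequence and replaces each position with the minimum
    image relative to its predecessor, so a molecule wrapped by the box
    becomes contiguous.  Suitable for backbone chains stored in bonded
    order; applied at read time so RMSD never sees wrapping jumps.
    Accepts a single frame (n, 3) or a stack (n_frames, n, 3).
    """
    coords = np.array(coordinates, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    deltas = coords[:, 1:] - coords[:, :-1]
    deltas = minimum_image(deltas, np.asarray(box, dtype=float))
    coords[:, 1:] = coords[:, [0]] + np.cumsum(deltas, axis=1)
    return coords[0] if single else coords
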
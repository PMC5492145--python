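"""Structure and trajectory readers/writers.

PDB (single- and multi-model), DCD and XTC go through MDAnalysis; this
module validates the records, applies the ion species table and converts
everything into the flexmd data model (Å, ns).  Tabular output is TSV with
a header row; estimate summaries are JSON.

Only orthorhombic boxes are supported; triclinic input raises
:class:`~flexmd.errors.UnsupportedFormatError`.
"""
from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AtomCountMismatchError,
    ParseError,
    UnsupportedFormatError,
)
from .model import (
    Atom,
    DEFAULT_SPECIES_TABLE,
    Frame,
    KNOWN_ION_NAMES,
    Topology,
    Trajectory,
)

logger = logging.getLogger(__name__)

_PS_PER_NS = 1000.0
#: Float precision used by write_table.
TABLE_FLOAT_FORMAT = "%.6g"


@dataclass
class Structure:
    """A parsed structure file: topology, first-model frame, model count."""

    topology: Topology
    frame: Frame
    n_models: int
    model_coordinates: np.ndarray  # (n_models, n_atoms, 3)


def _validate_pdb_lines(path: str) -> list[str]:
    """Pre-scan a PDB file.

    Checks that every ATOM/HETATM record parses under wwPDB v3.3 fixed
    columns, drops altloc records other than blank/'A' with a warning, and
    returns the retained lines.
    """
    kept: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                kept.append(line)
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    f"{rec} record shorter than the 54 columns needed for "
                    "coordinates", lineno,
                )
            try:
                int(line[6:11])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"malformed {rec} record: {exc}", lineno) from None
            altloc = line[16]
            if altloc not in (" ", "A"):
                logger.warning(
                    "skipping altloc %r record at line %d", altloc, lineno
                )
                continue
            kept.append(line)
    return kept


def read_structure(
    path: str, species_table: dict[str, int] | None = None
) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Ion valences come from `species_table` (residue name -> elementary
    charges); the shipped default covers K+, Cl-, Na+ and Zn2+.  A residue
    name that is a known ion but missing from the table raises — valence is
    never silently inferred.
    """
    import MDAnalysis as mda

    if species_table is None:
        species_table = dict(DEFAULT_SPECIES_TABLE)
    lines = _validate_pdb_lines(path)

    with tempfile.NamedTemporaryFile(
        "w", suffix=".pdb", delete=False
    ) as tmp:
        tmp.writelines(lines)
        tmp_path = tmp.name
    try:
        u = mda.Universe(tmp_path, format="PDB")
        atoms = []
        for a in u.atoms:
            resname = str(a.resname).strip()
            if resname in species_table:
                valence = int(species_table[resname])
            elif resname in KNOWN_ION_NAMES:
                raise ParseError(
                    f"ion residue {resname!r} has no species-table entry; "
                    "refusing to assign valence 0 silently"
                )
            else:
                valence = 0
            try:
                element = str(a.element).strip()
            except mda.exceptions.NoDataError:
                element = ""
            try:
                chain = str(a.chainID).strip()
            except mda.exceptions.NoDataError:
                chain = str(a.segid).strip()
            atoms.append(
                Atom(
                    serial=int(a.id),
                    name=str(a.name).strip(),
                    residue_name=resname,
                    residue_id=int(a.resid),
                    chain=chain,
                    element=element,
                    valence=valence,
                )
            )
        topology = Topology(atoms)
        n_models = len(u.trajectory)
        model_coords = np.empty((n_models, len(atoms), 3))
        for i, _ in enumerate(u.trajectory):
            model_coords[i] = u.atoms.positions
        box = _orthorhombic_box(u.trajectory.ts.dimensions, default=None)
        if box is None:
            # PDB without CRYST1: use a nominal large box
            box = np.array([1e6, 1e6, 1e6])
        frame = Frame(time=0.0, coordinates=model_coords[0], box=box)
        return Structure(topology, frame, n_models, model_coords)
    finally:
        os.unlink(tmp_path)


def _orthorhombic_box(dimensions, default="raise") -> np.ndarray | None:
    """Extract (Lx, Ly, Lz) from an MDAnalysis dimensions vector.

    Raises UnsupportedFormatError for triclinic cells.
    """
    if dimensions is None or np.all(dimensions[:3] == 0):
        if default == "raise":
            raise UnsupportedFormatError("frame has no box information")
        return None
    angles = np.asarray(dimensions[3:6], dtype=float)
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise UnsupportedFormatError(
            f"triclinic box (angles {angles}) is not supported; "
            "only orthorhombic cells are handled"
        )
    return np.asarray(dimensions[:3], dtype=float)


def read_trajectory(
    path: str,
    topology: Topology,
    dt: float | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """Read a DCD or XTC trajectory against an existing topology.

    Frame times are `t0 + i*dt` (ns) when `dt` is given; otherwise the
    file's own time stamps (ps, converted to ns) are used.  File formats
    rarely store a trustworthy time axis, so passing `dt` explicitly is
    recommended.
    """
    reader = _open_reader(path)
    if reader.n_atoms != topology.n_atoms:
        raise AtomCountMismatchError(
            f"trajectory {path!r} has {reader.n_atoms} atoms but topology "
            f"has {topology.n_atoms}"
        )
    coords, boxes, times = [], [], []
    i = 0
    try:
        for ts in reader:
            coords.append(np.array(ts.positions, dtype=float))
            boxes.append(_orthorhombic_box(ts.dimensions))
            if dt is not None:
                times.append(t0 + i * dt)
            else:
                times.append(float(ts.time) / _PS_PER_NS)
            i += 1
    except (EOFError, OSError, RuntimeError) as exc:
        raise ParseError(
            f"trajectory {path!r} truncated after frame {i - 1}: {exc}"
        ) from exc
    finally:
        reader.close()
    return Trajectory(topology, np.array(times), np.array(coords), np.array(boxes))


def _open_reader(path: str):
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    lower = path.lower()
    if lower.endswith(".dcd"):
        return DCDReader(path)
    if lower.endswith(".xtc"):
        return XTCReader(path)
    raise UnsupportedFormatError(
        f"cannot infer trajectory format from {path!r}; expected .dcd or .xtc"
    )


# ---------------------------------------------------------------------------
# Writing (round-trip support for the synthetic generators and the CLI)
# ---------------------------------------------------------------------------

def _mda_universe(topology: Topology, n_frames: int = 1):
    """Build an in-memory MDAnalysis Universe mirroring a flexmd Topology."""
    import MDAnalysis as mda

    resid_seq = topology.residue_ids
    # contiguous residue indices in file order
    res_keys: list[tuple] = []
    atom_resindex = np.empty(topology.n_atoms, dtype=int)
    for i in range(topology.n_atoms):
        key = (int(resid_seq[i]), str(topology.chains[i]))
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    n_res = len(res_keys)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        atom_resindex=atom_resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    resnames = [""] * n_res
    segids_per_res = [""] * n_res
    for i in range(topology.n_atoms):
        ri = atom_resindex[i]
        resnames[ri] = str(topology.residue_names[i])
        segids_per_res[ri] = str(topology.chains[i]) or "X"
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [k[0] for k in res_keys])
    u.add_TopologyAttr("chainIDs", [str(c) or "X" for c in topology.chains])
    u.add_TopologyAttr("ids", [int(s) for s in topology.serials])
    return u


def write_pdb(topology: Topology, frame: Frame, path: str) -> None:
    """Write a single-model PDB (topology + one coordinate set)."""
    import MDAnalysis as mda

    u = _mda_universe(topology)
    u.atoms.positions = frame.coordinates
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with mda.Writer(path, n_atoms=topology.n_atoms) as w:
        w.write(u.atoms)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory to DCD or XTC (round-trip support)."""
    import MDAnalysis as mda

    u = _mda_universe(traj.topology)
    with mda.Writer(path, n_atoms=traj.topology.n_atoms) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[i]
            u.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.frame = i
            w.write(u.atoms)


def write_table(records, path: str) -> None:
    """Write tabular records as TSV with a header row.

    `records` is a DataFrame or a list of dicts with uniform columns; an
    empty list yields a header-only file when column names are supplied via
    a DataFrame.  Floats are written at %.6g.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_summary(summary: dict, path: str) -> None:
    """Write an estimate/summary dict as deterministic, sorted-key JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
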
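"""In-memory data model: topology, frames, trajectories and channel geometry.

Units are Å for coordinates and box lengths, ns for time, mV for voltage,
elementary charges for ion valence.  Converters live at the I/O boundary
only; every analysis module assumes these units.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AtomCountMismatchError, ConfigError, SelectionError

#: Default ion species table mapping residue names to formal charge in
#: elementary-charge units.  Valence is never inferred from the element:
#: an ion residue name absent from the active table is a hard error.
DEFAULT_SPECIES_TABLE: dict[str, int] = {
    "K": +1,
    "POT": +1,
    "NA": +1,
    "SOD": +1,
    "CL": -1,
    "CLA": -1,
    "ZN": +2,
}

#: Residue names that are always ions; encountering one of these without a
#: species-table entry raises instead of silently assigning valence 0.
KNOWN_ION_NAMES = frozenset(DEFAULT_SPECIES_TABLE)


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str
    valence: int  # elementary charges; 0 for neutral atoms


class Topology:
    """Ordered atom list with vectorised per-field access.

    Atoms keep file order; selections by residue range return atoms in
    input order.
    """

    def __init__(self, atoms: list[Atom]):
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise SelectionError("duplicate atom serials in topology")
        self._atoms = list(atoms)
        self.serials = np.array(serials, dtype=int)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.chains = np.array([a.chain for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.valences = np.array([a.valence for a in atoms], dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def __len__(self) -> int:
        return len(self._atoms)

    def atom(self, index: int) -> Atom:
        return self._atoms[index]

    @property
    def atoms(self) -> list[Atom]:
        return list(self._atoms)

    def residue_index(self) -> dict[int, list[int]]:
        """Map residue_id -> atom indices (file order)."""
        index: dict[int, list[int]] = {}
        for i, rid in enumerate(self.residue_ids):
            index.setdefault(int(rid), []).append(i)
        return index

    # -- selections ----------------------------------------------------
    def select(
        self,
        residue_ids: range | list[int] | None = None,
        residue_names: set[str] | None = None,
        atom_names: set[str] | None = None,
        chains: set[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria, in file order."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_ids is not None:
            wanted = set(int(r) for r in residue_ids)
            mask &= np.array([int(r) in wanted for r in self.residue_ids])
        if residue_names is not None:
            mask &= np.isin(self.residue_names, list(residue_names))
        if atom_names is not None:
            mask &= np.isin(self.names, list(atom_names))
        if chains is not None:
            mask &= np.isin(self.chains, list(chains))
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One trajectory frame: time (ns), coordinates (Å) and box edges (Å)."""

    time: float
    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (Lx, Ly, Lz)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ConfigError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ConfigError("box must be three positive orthorhombic edge lengths")


class Trajectory:
    """Time-ordered frames sharing one topology.

    Stores coordinates as one (n_frames, n_atoms, 3) array for vectorised
    analysis; `frame(i)` yields a Frame view.
    """

    def __init__(
        self,
        topology: Topology,
        times: np.ndarray,
        coordinates: np.ndarray,
        boxes: np.ndarray,
    ):
        times = np.asarray(times, dtype=float)
        coordinates = np.asarray(coordinates, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ConfigError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coordinates.shape[1] != topology.n_atoms:
            raise AtomCountMismatchError(
                f"frames have {coordinates.shape[1]} atoms but topology has "
                f"{topology.n_atoms}"
            )
        if len(times) != coordinates.shape[0] or boxes.shape != (len(times), 3):
            raise ConfigError("times, coordinates and boxes must agree in frame count")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ConfigError("frame times must be strictly increasing")
        if np.any(boxes <= 0):
            raise ConfigError("box edge lengths must be positive")
        self.topology = topology
        self.times = times
        self.coordinates = coordinates
        self.boxes = boxes

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(self.times[i], self.coordinates[i], self.boxes[i])

    @property
    def duration(self) -> float:
        """Time spanned by the frames, ns."""
        return float(self.times[-1] - self.times[0])


@dataclass
class ChannelDefinition:
    """Channel geometry and electrical state.

    The pore axis is the box z axis.  The slab [z_lo, z_hi] spans the two
    channel mouths; an ion that moves from one reservoir to the other
    without a periodic wrap has crossed the channel.  Voltage is the
    potential applied along +z in mV.
    """

    z_lo: float
    z_hi: float
    voltage: float = 150.0  # mV
    pore_radius: float | None = None  # Å; None disables the radial gate
    axis_xy: tuple[float, float] = (0.0, 0.0)  # pore axis x, y position

    def __post_init__(self):
        if not self.z_lo < self.z_hi:
            raise ConfigError(f"z_lo ({self.z_lo}) must be < z_hi ({self.z_hi})")
        if self.pore_radius is not None and self.pore_radius <= 0:
            raise ConfigError("pore_radius must be positive")


def minimum_image(deltas: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Works for orthorhombic boxes only; `deltas` has shape (..., 3) or a
    single axis of scalars with a scalar box length.
    """
    return deltas - box * np.round(deltas / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points a and b (..., 3)."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), np.asarray(box, float))
    return np.sqrt(np.sum(d * d, axis=-1))
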
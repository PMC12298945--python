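"""Parameterized molecular systems and trajectories.

The static half of every calculation is a :class:`Topology`: an ordered
list of atoms carrying the per-atom parameters that end-point free energy
methods need (partial charges, Lennard-Jones well parameters, intrinsic
Born radii and descreening scales) together with a receptor/ligand
partition.  Standard structure formats do not transport these parameters,
so the canonical on-disk form is a small JSON schema; coordinates travel
as multi-model PDB.

Conventions: coordinates in Å, energies in kcal/mol, atom and residue
indices 0-based internally (1-based only at the PDB boundary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "TopologyError",
    "SelectionError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "select",
    "select_interface_residues",
]

SEGMENTS = ("receptor", "ligand")

#: named selectors understood by :func:`select`
SELECTORS = (
    "heavy_paper",
    "heavy_all",
    "calpha",
    "backbone",
    "segment:receptor",
    "segment:ligand",
)

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class TopologyError(ValueError):
    """Malformed or inconsistent topology input."""


class SelectionError(ValueError):
    """Unknown or invalid selection query."""


@dataclass(frozen=True)
class AtomRecord:
    """One parameterized atom.

    ``charge`` is the default-set partial charge (elementary charge
    units); alternative charge sets live on the owning topology.
    ``lj_rmin_half`` / ``lj_epsilon`` are the r_min/2 (Å) and well depth
    (kcal/mol) of the Lennard-Jones term; ``gb_radius`` / ``gb_screen``
    are the intrinsic Born radius (Å) and dimensionless descreening
    scale of the Generalized Born model.
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    segment: str
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    gb_radius: float
    gb_screen: float
    mass: float

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise TopologyError(
                f"atom {self.index}: segment must be one of {SEGMENTS}, "
                f"got {self.segment!r}"
            )
        if self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.index}: lj_epsilon must be >= 0")
        if self.element != "H" and self.gb_radius <= 0:
            raise TopologyError(
                f"atom {self.index}: gb_radius must be > 0 for heavy atoms"
            )


@dataclass(frozen=True, eq=False)
class Topology:
    """Ordered atom list with residue structure and named charge sets."""

    atoms: tuple[AtomRecord, ...]
    charge_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise TopologyError(
                    f"atom indices must be contiguous from 0; "
                    f"position {i} has index {atom.index}"
                )
        sets = dict(self.charge_sets)
        if "default" not in sets:
            sets["default"] = np.array([a.charge for a in self.atoms], dtype=float)
        for name, vec in sets.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.atoms),):
                raise TopologyError(
                    f"charge set {name!r} has {vec.size} entries for "
                    f"{len(self.atoms)} atoms"
                )
            sets[name] = vec
        object.__setattr__(self, "charge_sets", sets)

    # -- derived structure -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) + 1 if self.atoms else 0

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise KeyError(residue_index)

    def residue_atoms(self, residue_index: int) -> list[int]:
        return [a.index for a in self.atoms if a.residue_index == residue_index]

    def segment_indices(self, segment: str) -> np.ndarray:
        if segment not in SEGMENTS:
            raise TopologyError(f"unknown segment {segment!r}")
        return np.array(
            [a.index for a in self.atoms if a.segment == segment], dtype=int
        )

    def charges(self, charge_set: str = "default") -> np.ndarray:
        try:
            return self.charge_sets[charge_set]
        except KeyError:
            raise TopologyError(
                f"unknown charge set {charge_set!r}; "
                f"available: {sorted(self.charge_sets)}"
            ) from None

    def arrays(self) -> dict[str, np.ndarray]:
        """Per-atom parameter vectors as a dict of numpy arrays."""
        return {
            "lj_rmin_half": np.array([a.lj_rmin_half for a in self.atoms]),
            "lj_epsilon": np.array([a.lj_epsilon for a in self.atoms]),
            "gb_radius": np.array([a.gb_radius for a in self.atoms]),
            "gb_screen": np.array([a.gb_screen for a in self.atoms]),
            "mass": np.array([a.mass for a in self.atoms]),
        }


@dataclass(frozen=True, eq=False)
class Frame:
    """One set of Cartesian coordinates, Å, shape (n_atoms, 3)."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (N, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Ordered coordinate frames with recording interval and provenance."""

    frames: tuple[Frame, ...]
    frame_interval: float = 10.0  # ps between recorded frames
    replica_id: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}"
                )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "frames", tuple(self.frames))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    def window(self, start: int | None = None, stop: int | None = None,
               stride: int = 1) -> "Trajectory":
        sub = self.frames[slice(start, stop, stride)]
        if not sub:
            raise ValueError("frame window is empty after slicing")
        return replace(self, frames=sub)


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom index list with a label."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.atom_indices)
        if len(set(idx)) != len(idx):
            raise SelectionError(f"duplicate indices in selection {self.label!r}")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# topology JSON I/O

_ATOM_FIELDS = (
    "name", "element", "residue_index", "residue_name", "segment",
    "charge", "lj_rmin_half", "lj_epsilon", "gb_radius", "gb_screen", "mass",
)


def read_topology(path: str | Path) -> Topology:
    """Read a topology from the internal JSON schema."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TopologyError(f"not valid JSON: {exc}") from exc
    if "atoms" not in data:
        raise TopologyError("missing required key 'atoms'")
    atoms = []
    for i, raw in enumerate(data["atoms"]):
        missing = [f for f in _ATOM_FIELDS if f not in raw]
        if missing:
            raise TopologyError(f"atom {i}: missing field(s) {missing}")
        atoms.append(AtomRecord(index=i, **{f: raw[f] for f in _ATOM_FIELDS}))
    charge_sets = {
        name: np.asarray(vec, dtype=float)
        for name, vec in data.get("charge_sets", {}).items()
    }
    return Topology(atoms=tuple(atoms), charge_sets=charge_sets)


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write a topology in canonical (sorted-key, fixed-order) JSON form."""
    data = {
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS} for a in topology.atoms
        ],
        "charge_sets": {
            name: [float(q) for q in vec]
            for name, vec in sorted(topology.charge_sets.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# multi-model PDB I/O

def write_trajectory(trajectory: Trajectory, topology: Topology,
                     path: str | Path) -> None:
    """Write frames as a multi-model PDB (fixed-column ATOM records)."""
    lines: list[str] = []
    for m, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for atom, xyz in zip(topology.atoms, frame.coordinates):
            chain = "A" if atom.segment == "receptor" else "B"
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {atom.index + 1:5d} {name:<4.4s} "
                f"{atom.residue_name:<3.3s} {chain}{atom.residue_index + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, topology: Topology,
                    frame_interval: float = 10.0,
                    replica_id: int = 0) -> Trajectory:
    """Read a multi-model PDB into a trajectory bound to ``topology``."""
    frames: list[Frame] = []
    current: list[list[float]] = []
    in_model = False
    saw_model_record = False
    for line in Path(path).read_text().splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            in_model, saw_model_record, current = True, True, []
        elif rec == "ENDMDL":
            frames.append(_finish_model(current, topology, len(frames)))
            in_model, current = False, []
        elif rec in ("ATOM  ", "HETATM"):
            if not saw_model_record:
                in_model = True  # single-model file without MODEL records
            current.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if current:
        frames.append(_finish_model(current, topology, len(frames)))
    if not frames:
        raise ValueError(f"no models found in {path}")
    return Trajectory(frames=tuple(frames), frame_interval=frame_interval,
                      replica_id=replica_id, source=str(path))


def _finish_model(rows: list[list[float]], topology: Topology,
                  model_index: int) -> Frame:
    if len(rows) != topology.n_atoms:
        raise ValueError(
            f"model {model_index}: expected {topology.n_atoms} atoms, "
            f"found {len(rows)}"
        )
    return Frame(coordinates=np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# selections

def select(topology: Topology, query: str) -> Selection:
    """Resolve a named selector to an ordered atom-index selection.

    ``heavy_paper`` keeps C/N/O only (the narrow literal reading of
    "heavy atoms"); ``heavy_all`` keeps every non-hydrogen atom and is
    the recommended default. ``residue:<a>-<b>`` selects an inclusive
    0-based residue index range.
    """
    query = query.strip()
    if query == "heavy_paper":
        idx = [a.index for a in topology.atoms if a.element in ("C", "N", "O")]
    elif query == "heavy_all":
        idx = [a.index for a in topology.atoms if a.element != "H"]
    elif query == "calpha":
        idx = [a.index for a in topology.atoms if a.name == "CA"]
    elif query == "backbone":
        idx = [a.index for a in topology.atoms if a.name in _BACKBONE_NAMES]
    elif query.startswith("segment:"):
        seg = query.split(":", 1)[1]
        if seg not in SEGMENTS:
            raise SelectionError(
                f"unknown segment {seg!r}; supported selectors: "
                f"{SELECTORS + ('residue:<a>-<b>',)}"
            )
        idx = [a.index for a in topology.atoms if a.segment == seg]
    elif query.startswith("residue:"):
        spec_part = query.split(":", 1)[1]
        lo, _, hi = spec_part.partition("-")
        lo_i, hi_i = int(lo), int(hi if hi else lo)
        idx = [a.index for a in topology.atoms
               if lo_i <= a.residue_index <= hi_i]
    else:
        raise SelectionError(
            f"unknown selector {query!r}; supported: "
            f"{SELECTORS + ('residue:<a>-<b>',)}"
        )
    return Selection(atom_indices=tuple(idx), label=query)


def select_interface_residues(topology: Topology, frame: Frame,
                              cutoff: float = 5.0) -> list[int]:
    """Receptor residues whose minimum heavy-atom distance to any ligand
    heavy atom is ≤ ``cutoff`` (inclusive boundary), ascending order."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    lig = [a for a in topology.atoms
           if a.segment == "ligand" and a.element != "H"]
    if not lig:
        raise TopologyError("topology has no ligand heavy atoms")
    lig_xyz = frame.coordinates[[a.index for a in lig]]
    out: set[int] = set()
    for a in topology.atoms:
        if a.segment != "receptor" or a.element == "H":
            continue
        d = np.linalg.norm(lig_xyz - frame.coordinates[a.index], axis=1)
        if d.min() <= cutoff:
            out.add(a.residue_index)
    return sorted(out)
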
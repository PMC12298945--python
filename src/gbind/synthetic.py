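"""Seeded synthetic systems: toy receptor–ligand complexes, coordinate
ensembles with known covariance structure, and interaction-energy series
with known distributions.

These generators stand in for MD trajectories in tests and examples.
Frames are independent draws from the specified distribution (optionally
AR(1)-correlated to stress-test block error estimates), not integrated
dynamics: every estimator in this package is a functional of the
empirical distribution over frames, so i.i.d. sampling exercises all of
them with analytically known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, Frame, Selection, Topology, Trajectory

__all__ = [
    "EnsembleSpec",
    "EnergySeriesSpec",
    "ToyComplexSpec",
    "generate_ensemble",
    "generate_energy_series",
    "build_toy_complex",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Gaussian coordinate ensemble: mean structure plus displacements
    drawn from a specified covariance (Å²) over the selected atoms'
    stacked Cartesian coordinates."""

    reference: Frame
    covariance: np.ndarray
    n_frames: int
    seed: int
    selection: Selection | None = None  # None = all atoms
    ar1_phi: float = 0.0  # frame-to-frame correlation knob

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= abs(self.ar1_phi) < 1.0):
            raise ValueError("ar1_phi must satisfy |phi| < 1")


@dataclass(frozen=True)
class EnergySeriesSpec:
    """i.i.d. energy series (kcal/mol) from a named distribution.

    gaussian:   parameters {"mean", "sigma"}
    two_point:  parameters {"a"} — equally likely ±a about 0
    mixture:    parameters {"weights", "means", "sigmas"} — Gaussian mixture
    """

    distribution: str
    parameters: dict = field(default_factory=dict)
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ToyComplexSpec:
    """Small parameterized receptor–ligand complex.

    ``hbond_pairs`` lists (receptor residue index, ligand atom index)
    intents: each named residue gets a hydroxyl-like donor aimed at the
    named ligand atom, which is parameterized as an acceptor oxygen and
    placed at 2.85 Å donor–acceptor distance with a linear D–H···A
    geometry.
    """

    n_receptor_residues: int = 8
    ligand_atoms: int = 6
    hbond_pairs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 1 or self.ligand_atoms < 1:
            raise ValueError("need >= 1 residue and >= 1 ligand atom")
        for res, lig in self.hbond_pairs:
            if not (0 <= res < self.n_receptor_residues):
                raise ValueError(f"hbond residue {res} out of range")
            if not (0 <= lig < self.ligand_atoms):
                raise ValueError(f"hbond ligand atom {lig} out of range")


# ---------------------------------------------------------------------------

def generate_ensemble(spec: EnsembleSpec, topology: Topology) -> Trajectory:
    """Draw a coordinate ensemble around ``spec.reference``.

    Displacements of the selected atoms are multivariate normal with the
    specified covariance; unselected atoms stay at the reference.
    """
    sel = spec.selection
    idx = sel.indices if sel is not None else np.arange(topology.n_atoms)
    dim = 3 * len(idx)
    cov = np.asarray(spec.covariance, dtype=float)
    if cov.shape != (dim, dim):
        raise ValueError(
            f"covariance must be {dim}x{dim} for {len(idx)} selected atoms"
        )
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("covariance must be positive semi-definite")
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, dim))
    if spec.ar1_phi:
        phi = spec.ar1_phi
        out = np.empty_like(z)
        out[0] = z[0]
        for t in range(1, spec.n_frames):
            out[t] = phi * out[t - 1] + np.sqrt(1.0 - phi * phi) * z[t]
        z = out
    disp = z @ root.T

    ref = spec.reference.coordinates
    frames = []
    for t in range(spec.n_frames):
        coords = ref.copy()
        coords[idx] += disp[t].reshape(-1, 3)
        frames.append(Frame(coordinates=coords))
    return Trajectory(frames=tuple(frames), source=f"ensemble(seed={spec.seed})")


def generate_energy_series(spec: EnergySeriesSpec) -> np.ndarray:
    """Draw an i.i.d. energy series from the named distribution."""
    rng = np.random.default_rng(spec.seed)
    p = spec.parameters
    if spec.distribution == "gaussian":
        return p.get("mean", 0.0) + p.get("sigma", 1.0) * rng.standard_normal(
            spec.n_samples
        )
    if spec.distribution == "two_point":
        a = p.get("a", 1.0)
        return a * rng.choice([-1.0, 1.0], size=spec.n_samples)
    if spec.distribution == "mixture":
        weights = np.asarray(p["weights"], dtype=float)
        weights = weights / weights.sum()
        means = np.asarray(p["means"], dtype=float)
        sigmas = np.asarray(p["sigmas"], dtype=float)
        comp = rng.choice(len(weights), size=spec.n_samples, p=weights)
        return means[comp] + sigmas[comp] * rng.standard_normal(spec.n_samples)
    raise ValueError(
        f"unknown distribution {spec.distribution!r}; "
        "supported: gaussian, two_point, mixture"
    )


# ---------------------------------------------------------------------------
# toy complex construction

# Amber-flavoured parameter blocks (charge e, rmin/2 Å, eps kcal/mol,
# Born radius Å, screen, mass amu)
_PARAMS = {
    "N":  dict(charge=-0.4157, lj_rmin_half=1.8240, lj_epsilon=0.1700,
               gb_radius=1.55, gb_screen=0.79, mass=14.007),
    "CA": dict(charge=0.0337, lj_rmin_half=1.9080, lj_epsilon=0.1094,
               gb_radius=1.70, gb_screen=0.72, mass=12.011),
    "C":  dict(charge=0.5973, lj_rmin_half=1.9080, lj_epsilon=0.0860,
               gb_radius=1.70, gb_screen=0.72, mass=12.011),
    "O":  dict(charge=-0.5679, lj_rmin_half=1.6612, lj_epsilon=0.2100,
               gb_radius=1.50, gb_screen=0.85, mass=15.999),
    "CB": dict(charge=-0.1825, lj_rmin_half=1.9080, lj_epsilon=0.1094,
               gb_radius=1.70, gb_screen=0.72, mass=12.011),
    # nonpolar gamma carbon carries the charge of the hydrogen that
    # replaces it on mutation to alanine, so remote mutations are
    # electrostatically near-silent
    "CG": dict(charge=0.0603, lj_rmin_half=1.9080, lj_epsilon=0.1094,
               gb_radius=1.70, gb_screen=0.72, mass=12.011),
    "OG": dict(charge=-0.6546, lj_rmin_half=1.7210, lj_epsilon=0.2104,
               gb_radius=1.50, gb_screen=0.85, mass=15.999),
    "HG": dict(charge=0.4275, lj_rmin_half=0.6000, lj_epsilon=0.0157,
               gb_radius=1.20, gb_screen=0.85, mass=1.008),
}

_LIG_C = dict(lj_rmin_half=1.9080, lj_epsilon=0.0860,
              gb_radius=1.70, gb_screen=0.72, mass=12.011)
_LIG_O = dict(lj_rmin_half=1.6612, lj_epsilon=0.2100,
              gb_radius=1.50, gb_screen=0.85, mass=15.999)

_RES_SPACING = 4.2  # Angstrom between consecutive Calpha positions
_MIN_DIST = 1.0


def build_toy_complex(spec: ToyComplexSpec) -> tuple[Topology, Frame]:
    """Build a parameterized toy complex with requested hydrogen bonds.

    The receptor is an extended strand of simplified residues (backbone
    N/CA/C/O plus a CB–CG stub side chain); residues named in
    ``hbond_pairs`` carry a serine-like hydroxyl aimed at their target
    ligand atom.  The ligand is a compact neutral cluster of carbons
    with acceptor oxygens at the hydrogen-bond target positions.  No two
    atoms sit closer than 1 Å; donor–acceptor distances are 2.85 Å with
    D–H···A of 180°.
    """
    rng = np.random.default_rng(spec.seed)
    donors = {res: lig for res, lig in spec.hbond_pairs}
    if len(donors) != len(spec.hbond_pairs):
        raise ValueError("at most one hydrogen-bond intent per residue")

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    lig_targets: dict[int, np.ndarray] = {}  # ligand atom -> position

    def add(name: str, element: str, res_i: int, res_name: str, segment: str,
            xyz: np.ndarray, **params) -> None:
        atoms.append(AtomRecord(
            index=len(atoms), name=name, element=element,
            residue_index=res_i, residue_name=res_name, segment=segment,
            **params))
        coords.append(np.asarray(xyz, dtype=float))

    down = np.array([0.0, -1.0, 0.0])
    for i in range(spec.n_receptor_residues):
        # slight zig-zag keeps the Calpha trace non-collinear
        ca = np.array([_RES_SPACING * i, 0.0, 0.35 * (i % 2)])
        res_name = "SER" if i in donors else "LEU"
        add("N", "N", i, res_name, "receptor",
            ca + [-1.45, 0.5, 0.8], **_PARAMS["N"])
        add("CA", "C", i, res_name, "receptor", ca, **_PARAMS["CA"])
        add("C", "C", i, res_name, "receptor",
            ca + [1.45, 0.5, 0.8], **_PARAMS["C"])
        add("O", "O", i, res_name, "receptor",
            ca + [1.45, 1.7, 0.8], **_PARAMS["O"])
        cb = ca + 1.53 * down
        add("CB", "C", i, res_name, "receptor", cb, **_PARAMS["CB"])
        if i in donors:
            og = cb + 1.41 * down
            add("OG", "O", i, res_name, "receptor", og, **_PARAMS["OG"])
            add("HG", "H", i, res_name, "receptor",
                og + 1.00 * down, **_PARAMS["HG"])
            lig_targets[donors[i]] = og + 2.85 * down  # linear D-H...A
        else:
            add("CG", "C", i, res_name, "receptor",
                cb + 1.53 * down, **_PARAMS["CG"])

    # ligand: each acceptor oxygen pinned at its hydrogen-bond target
    # with a carbonyl-like partner carbon 1.23 Å behind it (so the
    # donor sees a dipole, as in real carbonyl/carboxylate acceptors);
    # remaining atoms are neutral carbons on a jittered grid
    n_acc = len(lig_targets)
    q_acc, q_carbonyl = -0.55, 0.55
    if spec.ligand_atoms < 2 * n_acc:
        raise ValueError(
            f"{n_acc} hydrogen-bond intents need >= {2 * n_acc} ligand "
            f"atoms (acceptor + partner carbon each)")
    anchor_res = max(spec.n_receptor_residues - 2, 0)
    anchor = np.array([_RES_SPACING * anchor_res, -8.2, 0.0])
    taken = np.array(coords)
    placed: dict[int, np.ndarray] = dict(lig_targets)
    partners: dict[int, np.ndarray] = {}
    free_slots = [j for j in range(spec.ligand_atoms) if j not in placed]
    for j in sorted(lig_targets):
        partners[free_slots.pop(0)] = lig_targets[j] + 1.23 * down
    placed.update(partners)
    grid = iter(_ligand_grid(anchor, rng))
    for j in range(spec.ligand_atoms):
        if j in placed:
            continue
        for candidate in grid:
            ok_prev = all(np.linalg.norm(candidate - p) >= 1.45
                          for p in placed.values())
            ok_rec = np.min(np.linalg.norm(taken - candidate, axis=1)) >= 2.5
            if ok_prev and ok_rec:
                placed[j] = candidate
                break
        else:
            raise ValueError("could not place ligand atoms without clashes")

    lig_res = spec.n_receptor_residues
    for j in range(spec.ligand_atoms):
        if j in lig_targets:
            add(f"O{j + 1}", "O", lig_res, "LIG", "ligand",
                placed[j], charge=q_acc, **_LIG_O)
        elif j in partners:
            add(f"C{j + 1}", "C", lig_res, "LIG", "ligand",
                placed[j], charge=q_carbonyl, **_LIG_C)
        else:
            add(f"C{j + 1}", "C", lig_res, "LIG", "ligand",
                placed[j], charge=0.0, **_LIG_C)

    frame = Frame(coordinates=np.array(coords))
    d = frame.coordinates[:, None, :] - frame.coordinates[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() < _MIN_DIST - 1e-9:
        raise ValueError("internal clash in generated geometry")
    return Topology(atoms=tuple(atoms)), frame


def _ligand_grid(anchor: np.ndarray, rng: np.random.Generator):
    """Deterministic jittered grid of candidate ligand positions."""
    offsets = []
    for dz in (0.0, 1.6, -1.6):
        for dy in (0.0, -1.6, 1.6, -3.2):
            for dx in (0.0, 1.6, -1.6, 3.2, -3.2):
                offsets.append(np.array([dx, dy, dz]))
    for off in offsets:
        yield anchor + off + rng.uniform(-0.05, 0.05, size=3)
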
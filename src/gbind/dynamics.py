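"""Structural analytics over trajectory ensembles.

Kabsch superposition with RMSD/RMSF, hydrogen-bond occupancy counting,
dynamic cross-correlation matrices (DCCM) of Cα displacements,
principal component analysis of the Cartesian covariance, and K-means
conformational clustering with representative-frame extraction.

Frames are least-squares aligned before any fluctuation statistic is
taken, so all outputs are invariant under rigid motions of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import Frame, Selection, Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsfProfile",
    "HBondCriteria",
    "HBondOccupancy",
    "CorrelationMatrix",
    "PcaResult",
    "ClusterResult",
    "superpose",
    "rmsd_series",
    "rmsf",
    "hbond_occupancy",
    "dccm",
    "pca",
    "kmeans_cluster",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit: x_fit = (x_mobile - centroid_m) @ R + centroid_r."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue fluctuation with cross-replica standard error, Å."""

    residue_indices: np.ndarray
    rmsf: np.ndarray
    standard_error: np.ndarray
    per_replica: np.ndarray  # (n_replicas, n_residues)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor–acceptor heavy-atom
    distance cutoff (Å) and minimum D–H···A angle (degrees)."""

    max_da_distance: float = 3.5
    min_dha_angle: float = 135.0


@dataclass(frozen=True)
class HBondOccupancy:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    occupancy: float
    label: str = ""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Normalized residue-displacement cross-correlations in [-1, 1]."""

    matrix: np.ndarray
    residue_indices: np.ndarray


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray        # descending, Å²
    eigenvectors: np.ndarray       # columns, shape (3m, n_components)
    variance_fractions: np.ndarray  # of the full spectrum
    projections: np.ndarray        # (n_frames, n_components)


@dataclass(frozen=True)
class ClusterResult:
    k: int
    labels: np.ndarray
    populations: np.ndarray
    representative_frames: np.ndarray
    inertia: float


# ---------------------------------------------------------------------------
# superposition

def superpose(mobile: Frame | np.ndarray, reference: Frame | np.ndarray,
              sel: Selection | None = None,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Kabsch least-squares rigid superposition of mobile onto reference.

    Returns the proper rotation (det +1), translation, and the
    minimized RMSD over the selected atoms.
    """
    xm = mobile.coordinates if isinstance(mobile, Frame) else np.asarray(mobile)
    xr = reference.coordinates if isinstance(reference, Frame) else np.asarray(reference)
    if sel is not None:
        xm, xr = xm[sel.indices], xr[sel.indices]
    if len(xm) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    w = np.ones(len(xm)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()

    cm = (w[:, None] * xm).sum(axis=0)
    cr = (w[:, None] * xr).sum(axis=0)
    am, ar = xm - cm, xr - cr
    h = am.T @ (w[:, None] * ar)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):  # rank < 2: collinear selection
        raise ValueError("selected atoms are collinear; fit is degenerate")
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    fitted = am @ rot
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - ar) ** 2)))
    return SuperpositionResult(rotation=rot, translation=cr, rmsd=rmsd)


def _aligned_coords(trajectory: Trajectory, reference: np.ndarray,
                    sel: Selection) -> np.ndarray:
    """All-atom coordinates of every frame after fitting the selection
    onto the reference selection coordinates."""
    out = np.empty((trajectory.n_frames, trajectory.n_atoms, 3))
    ref_sel = reference[sel.indices]
    for t, frame in enumerate(trajectory.frames):
        fit = superpose(frame.coordinates[sel.indices], ref_sel)
        cm = frame.coordinates[sel.indices].mean(axis=0)
        out[t] = (frame.coordinates - cm) @ fit.rotation + fit.translation
    return out


def rmsd_series(trajectory: Trajectory, reference: Frame,
                sel: Selection) -> np.ndarray:
    """Per-frame minimized RMSD (Å) against a fixed reference."""
    return np.array([
        superpose(frame, reference, sel).rmsd for frame in trajectory.frames
    ])


def rmsf(trajectories: list[Trajectory] | Trajectory, sel: Selection,
         topology: Topology | None = None,
         reference: Frame | None = None, align: bool = True) -> RmsfProfile:
    """Per-residue RMSF with cross-replica standard error.

    Each replica is aligned to its mean structure by a two-pass fit
    (align to first frame, recompute mean, re-align, measure), then
    RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) per selected atom; atoms sharing a
    residue are averaged.  The profile is the cross-replica mean with
    SEM across replicas (zero for a single replica).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    idx = sel.indices
    if topology is not None:
        res_of = np.array([topology.atoms[i].residue_index for i in idx])
    else:
        res_of = np.arange(len(idx))
    residues = np.unique(res_of)

    per_rep = []
    for traj in trajectories:
        if align:
            ref = (reference.coordinates if reference is not None
                   else traj.frames[0].coordinates)
            aligned = _aligned_coords(traj, ref, sel)[:, idx, :]
            mean = aligned.mean(axis=0)
            # second pass: re-fit to the mean structure
            realigned = np.empty_like(aligned)
            for t in range(aligned.shape[0]):
                fit = superpose(aligned[t], mean)
                realigned[t] = (
                    (aligned[t] - aligned[t].mean(axis=0)) @ fit.rotation
                    + fit.translation)
        else:
            realigned = traj.coordinates()[:, idx, :]
        mean = realigned.mean(axis=0)
        per_atom = np.sqrt(
            np.mean(np.sum((realigned - mean) ** 2, axis=2), axis=0))
        per_res = np.array([per_atom[res_of == r].mean() for r in residues])
        per_rep.append(per_res)
    per_rep = np.array(per_rep)
    mean_prof = per_rep.mean(axis=0)
    if len(per_rep) > 1:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(len(per_rep))
    else:
        se = np.zeros_like(mean_prof)
    return RmsfProfile(residue_indices=residues, rmsf=mean_prof,
                       standard_error=se, per_replica=per_rep)


# ---------------------------------------------------------------------------
# hydrogen bonds

_H_COVALENT_CUTOFF = 1.3  # Angstrom: hydrogen counted as bonded to donor


def hbond_occupancy(topology: Topology, trajectory: Trajectory,
                    criteria: HBondCriteria | None = None,
                    donors: Selection | None = None,
                    acceptors: Selection | None = None,
                    ) -> list[HBondOccupancy]:
    """Occupancy fraction of every donor/acceptor pairing over frames.

    A bond counts in a frame iff the donor–acceptor heavy distance is
    ≤ the cutoff and the D–H···A angle ≥ the minimum, for any hydrogen
    covalently attached to the donor (≤ 1.3 Å in that frame).  Donors
    default to receptor N/O with an attached hydrogen; acceptors to
    ligand N/O.  Pairs are returned ranked by occupancy (ties by donor
    then acceptor index); donors with no resolvable hydrogen are
    skipped with a warning.
    """
    criteria = criteria or HBondCriteria()
    warn_missing_h = donors is not None
    if donors is None:
        # auto-selection: receptor N/O that actually carry a hydrogen
        # in the first frame (others are silently non-donors)
        x0 = trajectory.frames[0].coordinates
        h_idx = np.array([a.index for a in topology.atoms
                          if a.element == "H"], dtype=int)
        cand = []
        for a in topology.atoms:
            if a.segment == "receptor" and a.element in ("N", "O"):
                if h_idx.size and np.any(
                        np.linalg.norm(x0[h_idx] - x0[a.index], axis=1)
                        <= _H_COVALENT_CUTOFF):
                    cand.append(a.index)
        donors = Selection(tuple(cand), label="receptor donors")
    if acceptors is None:
        acceptors = Selection(tuple(
            a.index for a in topology.atoms
            if a.segment == "ligand" and a.element in ("N", "O")),
            label="ligand N/O")
    hydrogens = np.array([a.index for a in topology.atoms
                          if a.element == "H"], dtype=int)
    cos_min = np.cos(np.deg2rad(criteria.min_dha_angle))

    counts: dict[tuple[int, int, int], int] = {}
    skipped: set[int] = set()
    for frame in trajectory.frames:
        x = frame.coordinates
        for d in donors.atom_indices:
            if hydrogens.size:
                hd = np.linalg.norm(x[hydrogens] - x[d], axis=1)
                attached = hydrogens[hd <= _H_COVALENT_CUTOFF]
            else:
                attached = np.array([], dtype=int)
            if attached.size == 0:
                skipped.add(d)
                continue
            for a in acceptors.atom_indices:
                if a == d:
                    continue
                if np.linalg.norm(x[a] - x[d]) > criteria.max_da_distance:
                    continue
                for h in attached:
                    v1 = x[d] - x[h]
                    v2 = x[a] - x[h]
                    cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if cos <= cos_min:  # angle >= minimum
                        key = (int(d), int(h), int(a))
                        counts[key] = counts.get(key, 0) + 1
                        break
    if warn_missing_h:
        for d in sorted(skipped):
            warnings.warn(f"donor atom {d} has no attached hydrogen; skipped",
                          RuntimeWarning, stacklevel=2)

    def label(i: int) -> str:
        a = topology.atoms[i]
        return f"{a.residue_name}{a.residue_index}:{a.name}"

    out = [
        HBondOccupancy(donor_index=d, hydrogen_index=h, acceptor_index=a,
                       occupancy=c / trajectory.n_frames,
                       label=f"{label(d)}->{label(a)}")
        for (d, h, a), c in counts.items()
    ]
    out.sort(key=lambda b: (-b.occupancy, b.donor_index, b.acceptor_index))
    return out


# ---------------------------------------------------------------------------
# collective motions

def _pooled_displacements(trajectories: list[Trajectory] | Trajectory,
                          sel: Selection, reference: Frame | None,
                          align: bool = True) -> tuple[np.ndarray, int]:
    """Selected-atom coordinates pooled over replicas, RMS-fit per
    replica unless ``align=False`` (pre-aligned input), shape
    (total_frames, m, 3)."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    pools = []
    for traj in trajectories:
        if align:
            ref = (reference.coordinates if reference is not None
                   else traj.frames[0].coordinates)
            pools.append(_aligned_coords(traj, ref, sel)[:, sel.indices, :])
        else:
            pools.append(traj.coordinates()[:, sel.indices, :])
    coords = np.concatenate(pools, axis=0)
    return coords, len(trajectories)


def dccm(trajectories: list[Trajectory] | Trajectory, sel: Selection,
         topology: Topology | None = None,
         reference: Frame | None = None,
         align: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of selected-atom displacements.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) over pooled aligned
    frames, where Δr is the displacement from the pooled mean position.
    Zero-variance atoms get zero off-diagonal entries (the ratio is
    undefined) with a warning; the diagonal is exactly 1.
    """
    coords, _ = _pooled_displacements(trajectories, sel, reference, align)
    disp = coords - coords.mean(axis=0)
    inner = np.einsum("tik,tjk->ij", disp, disp) / coords.shape[0]
    var = np.diag(inner).copy()
    dead = var <= 1e-300
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance atom(s) in DCCM",
                      RuntimeWarning, stacklevel=2)
        var[dead] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    if topology is not None:
        res = np.array([topology.atoms[i].residue_index
                        for i in sel.indices])
    else:
        res = np.arange(len(sel))
    return CorrelationMatrix(matrix=c, residue_indices=res)


def pca(trajectories: list[Trajectory] | Trajectory, sel: Selection,
        n_components: int = 3,
        reference: Frame | None = None, align: bool = True) -> PcaResult:
    """Eigen-decomposition of the 3m×3m Cartesian covariance of the
    selected atoms over pooled aligned frames, with per-frame
    projections onto the leading components."""
    coords, _ = _pooled_displacements(trajectories, sel, reference, align)
    flat = coords.reshape(coords.shape[0], -1)
    if n_components > flat.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds 3m={flat.shape[1]}")
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        eigenvalues=evals[:n_components],
        eigenvectors=evecs[:, :n_components],
        variance_fractions=fractions,
        projections=centered @ evecs[:, :n_components],
    )


def kmeans_cluster(trajectories: list[Trajectory] | Trajectory,
                   sel: Selection, k: int = 3, seed: int = 0,
                   reference: Frame | None = None,
                   align: bool = True) -> ClusterResult:
    """K-means conformational clustering on aligned coordinates.

    Frames are RMS-fit to a common reference so Euclidean distance in
    flattened coordinate space approximates pairwise RMSD, then
    clustered with k-means++ seeding.  Cluster labels are canonicalized
    by descending population; the representative of each cluster is the
    member frame nearest its centroid (lowest index on ties).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if reference is None:
        reference = trajectories[0].frames[0]
    coords, _ = _pooled_displacements(trajectories, sel, reference, align)
    flat = coords.reshape(coords.shape[0], -1)
    n = flat.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(flat)
    raw = km.labels_

    pops = np.array([(raw == c).sum() for c in range(k)], dtype=float)
    order = np.lexsort((np.arange(k), -pops))  # descending pop, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    populations = pops[order] / n

    reps = np.empty(k, dtype=int)
    for new_c, old_c in enumerate(order):
        members = np.where(raw == old_c)[0]
        d = np.linalg.norm(flat[members] - km.cluster_centers_[old_c], axis=1)
        reps[new_c] = members[np.argmin(d)]  # argmin takes lowest on ties
    return ClusterResult(k=k, labels=labels, populations=populations,
                         representative_frames=reps,
                         inertia=float(km.inertia_))
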
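"""Per-frame energy kernels for end-point free energy analysis.

Four kernels: intermolecular Coulomb and Lennard-Jones sums (the
gas-phase molecular-mechanics terms), OBC-II Generalized Born polar
solvation, and Shrake–Rupley solvent-accessible surface area feeding the
linear nonpolar solvation model ΔG_np = γ·ΔSASA + β.

All energies in kcal/mol, lengths in Å, charges in elementary charge
units.  The Coulomb constant is the Amber convention
k_e = 332.0637 kcal·Å/(mol·e²).  Post-processing uses no distance
cutoffs: every pair contributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Selection, Topology

__all__ = [
    "COULOMB_CONSTANT",
    "GBParams",
    "SasaParams",
    "EnergyComponents",
    "coulomb_energy",
    "lj_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "gb_cross_energy",
    "sasa",
    "nonpolar_energy",
]

COULOMB_CONSTANT = 332.0637  # kcal*Angstrom/(mol*e^2)

_MIN_PAIR_DISTANCE = 1e-6


@dataclass(frozen=True)
class GBParams:
    """OBC-II Generalized Born parameters.

    ``radius_offset`` is the uniform reduction applied to intrinsic Born
    radii before the descreening integral (0.09 Å, the common Amber
    choice); ``obc_alpha/beta/gamma`` are the OBC-II tanh-rescaling
    constants (1.0, 0.8, 4.85).
    """

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 78.5
    radius_offset: float = 0.09
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85

    def __post_init__(self) -> None:
        if not (self.exterior_dielectric > self.interior_dielectric > 0):
            raise ValueError("require exterior > interior > 0 dielectrics")


@dataclass(frozen=True)
class SasaParams:
    """Nonpolar solvation parameters: surface tension gamma
    (kcal/mol/Å²), constant offset (kcal/mol), water-probe radius (Å),
    and the Shrake–Rupley quadrature density."""

    gamma: float = 0.0072
    beta_offset: float = 0.0
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.probe_radius < 0:
            raise ValueError("gamma and probe_radius must be >= 0")


@dataclass(frozen=True)
class EnergyComponents:
    """One frame's binding energy components, kcal/mol."""

    e_ele: float
    e_vdw: float
    g_gb: float
    g_np: float

    @property
    def total(self) -> float:
        return self.e_ele + self.e_vdw + self.g_gb + self.g_np


def _pair_setup(topology: Topology, frame: Frame, sel_a: Selection,
                sel_b: Selection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ia, ib = sel_a.indices, sel_b.indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections must be disjoint")
    xa, xb = frame.coordinates[ia], frame.coordinates[ib]
    r = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    if r.size and r.min() < _MIN_PAIR_DISTANCE:
        raise ValueError("coincident atoms across selections")
    return ia, ib, r


def coulomb_energy(topology: Topology, frame: Frame, sel_a: Selection,
                   sel_b: Selection, charge_set: str = "default") -> float:
    """Pairwise Coulomb energy between two disjoint selections, no cutoff."""
    ia, ib, r = _pair_setup(topology, frame, sel_a, sel_b)
    q = topology.charges(charge_set)
    return float(COULOMB_CONSTANT * np.sum(np.outer(q[ia], q[ib]) / r))


def lj_energy(topology: Topology, frame: Frame, sel_a: Selection,
              sel_b: Selection) -> float:
    """12-6 Lennard-Jones energy with Lorentz–Berthelot-style combination:
    r_min,ij = r_min,i/2 + r_min,j/2 and ε_ij = √(ε_i ε_j)."""
    ia, ib, r = _pair_setup(topology, frame, sel_a, sel_b)
    p = topology.arrays()
    rmin = p["lj_rmin_half"][ia][:, None] + p["lj_rmin_half"][ib][None, :]
    eps = np.sqrt(np.outer(p["lj_epsilon"][ia], p["lj_epsilon"][ib]))
    s6 = (rmin / r) ** 6
    return float(np.sum(eps * (s6 * s6 - 2.0 * s6)))


# ---------------------------------------------------------------------------
# Generalized Born (OBC-II)

def effective_born_radii(topology: Topology, frame: Frame,
                         params: GBParams, sel: Selection) -> np.ndarray:
    """OBC-II effective Born radii for the selected atoms, Å.

    Pairwise HCT descreening integrals are accumulated into Ψ and mapped
    through the OBC tanh rescaling; an isolated atom recovers its
    offset-reduced intrinsic radius ρ − offset.
    """
    idx = sel.indices
    p = topology.arrays()
    rho = p["gb_radius"][idx]
    if np.any(rho <= 0):
        raise ValueError("all selected atoms need positive intrinsic radii")
    screen = p["gb_screen"][idx]
    rho_red = rho - params.radius_offset  # offset-reduced radii
    if np.any(rho_red <= 0):
        raise ValueError("radius_offset exceeds an intrinsic radius")
    x = frame.coordinates[idx]
    n = len(idx)
    if n > 1:
        diff = x[:, None, :] - x[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        np.fill_diagonal(r, np.inf)  # excluded from the pair sum below
        srj = (screen * rho_red)[None, :]
        rho_i = rho_red[:, None]
        upper = r + srj
        lower = np.maximum(np.abs(r - srj), rho_i)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = 0.5 * (
                1.0 / lower - 1.0 / upper
                + 0.25 * (r - srj ** 2 / r)
                * (1.0 / upper ** 2 - 1.0 / lower ** 2)
                + 0.5 / r * np.log(lower / upper)
            )
            term += np.where(rho_i < srj - r, 1.0 / rho_i - 1.0 / lower, 0.0)
        term = np.where(upper <= rho_i, 0.0, term)  # j engulfed by i
        np.fill_diagonal(term, 0.0)
        integral = term.sum(axis=1)
    else:
        integral = np.zeros(n)
    psi = integral * rho_red
    arg = (params.obc_alpha * psi - params.obc_beta * psi ** 2
           + params.obc_gamma * psi ** 3)
    inv_radius = 1.0 / rho_red - np.tanh(arg) / rho
    return 1.0 / inv_radius


def _hct_term(r: float, rho_i: float, s_rho_j: float) -> float:
    """HCT pairwise descreening integral of atom j (scaled radius
    ``s_rho_j``) over the solvent-excluded region seen from atom i."""
    if r + s_rho_j <= rho_i:  # j fully engulfed by i: no descreening
        return 0.0
    upper = r + s_rho_j
    lower = max(abs(r - s_rho_j), rho_i)
    term = 0.5 * (
        1.0 / lower - 1.0 / upper
        + 0.25 * (r - s_rho_j ** 2 / r) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
        + 0.5 / r * np.log(lower / upper)
    )
    if rho_i < s_rho_j - r:  # i buried inside j's descreening sphere
        term += 1.0 / rho_i - 1.0 / lower
    return term


def _gb_pair_function(r2: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Smooth GB pair function f_GB = sqrt(r² + RᵢRⱼ exp(−r²/(4RᵢRⱼ)))."""
    rr = np.outer(radii, radii)
    return np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))


def gb_polar_energy(topology: Topology, frame: Frame, params: GBParams,
                    sel: Selection, charge_set: str = "default",
                    radii: np.ndarray | None = None) -> float:
    """Total GB polar solvation energy of a selection (self + pair terms).

    E = −(k_e/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j),
    the double sum including i = j where f_GB = R_i.
    """
    idx = sel.indices
    if radii is None:
        radii = effective_born_radii(topology, frame, params, sel)
    q = topology.charges(charge_set)[idx]
    x = frame.coordinates[idx]
    diff = x[:, None, :] - x[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    fgb = _gb_pair_function(r2, radii)
    pref = -0.5 * COULOMB_CONSTANT * (
        1.0 / params.interior_dielectric - 1.0 / params.exterior_dielectric
    )
    return float(pref * np.sum(np.outer(q, q) / fgb))


def gb_cross_energy(topology: Topology, frame: Frame, params: GBParams,
                    sel: Selection, group_a: np.ndarray, group_b: np.ndarray,
                    charge_set: str = "default",
                    radii: np.ndarray | None = None) -> float:
    """GB pair energy between two disjoint atom groups evaluated with the
    whole-selection effective radii (used by per-residue decomposition).

    Counts each cross pair once with the full (not half) prefactor, i.e.
    the (a,b)+(b,a) share of the symmetric double sum.
    """
    idx = sel.indices
    if radii is None:
        radii = effective_born_radii(topology, frame, params, sel)
    pos = {int(a): k for k, a in enumerate(idx)}
    ka = np.array([pos[int(a)] for a in group_a], dtype=int)
    kb = np.array([pos[int(b)] for b in group_b], dtype=int)
    q = topology.charges(charge_set)[idx]
    x = frame.coordinates[idx]
    diff = x[ka][:, None, :] - x[kb][None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    rr = np.outer(radii[ka], radii[kb])
    fgb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -COULOMB_CONSTANT * (
        1.0 / params.interior_dielectric - 1.0 / params.exterior_dielectric
    )
    return float(pref * np.sum(np.outer(q[ka], q[kb]) / fgb))


# ---------------------------------------------------------------------------
# solvent-accessible surface area

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(topology: Topology, frame: Frame, params: SasaParams,
         sel: Selection, radii: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²) by Shrake–Rupley
    quadrature over the selected atoms only.

    Atomic radii default to the topology's intrinsic Born radii; the
    accessible sphere of each atom has radius (atom + probe).
    """
    if params.n_sphere_points < 12:
        raise ValueError("n_sphere_points must be >= 12")
    idx = sel.indices
    if radii is None:
        radii = topology.arrays()["gb_radius"][idx]
    radii = np.asarray(radii, dtype=float) + params.probe_radius
    x = frame.coordinates[idx]
    unit = _sphere_points(params.n_sphere_points)
    n = len(idx)
    areas = np.zeros(n)
    r2 = radii ** 2
    for i in range(n):
        pts = x[i] + radii[i] * unit
        # neighbors that can possibly occlude points on sphere i
        d_ij = np.linalg.norm(x - x[i], axis=1)
        near = np.where((d_ij < radii[i] + radii)
                        & (np.arange(n) != i))[0]
        if near.size:
            xn = x[near]
            # squared point-neighbor distances via one GEMM
            d2 = (
                np.einsum("pk,pk->p", pts, pts)[:, None]
                - 2.0 * pts @ xn.T
                + np.einsum("jk,jk->j", xn, xn)[None, :]
            )
            exposed = np.all(d2 > r2[near][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r2[i] * frac
    return areas


def nonpolar_energy(delta_sasa: float, params: SasaParams) -> float:
    """Linear nonpolar solvation term γ·ΔSASA + β."""
    return params.gamma * delta_sasa + params.beta_offset
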
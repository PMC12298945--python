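"""MM/GBSA + interaction-entropy binding free energy pipeline.

The binding free energy is assembled as ΔG_bind = ΔH + (−TΔS):

* ΔH from end-point MM/GBSA under the single-trajectory protocol —
  receptor and ligand conformations are extracted from the complex
  frames, so intramolecular gas-phase terms cancel and
  ΔH = ΔE_ele + ΔE_vdW + ΔG_gb + ΔG_np is averaged over frames.
* −TΔS from the interaction-entropy (IE) estimator
  −TΔS = kT·ln⟨exp(βΔE_pl^int)⟩, where ΔE_pl^int is the fluctuation of
  the gas-phase receptor–ligand interaction energy about its mean.

On top sit replica averaging with SEM bookkeeping, per-residue
decomposition with hot-spot calling, and alanine-scanning interaction
entropy (ASIE): mutate a residue to alanine on the wild-type frames and
recompute both ΔH and −TΔS, reporting ΔΔG = ΔG^wild − ΔG^ala (under
this sign convention hot spots come out negative).

The statsmodels-style entry point is :class:`BindingFreeEnergy` /
:class:`BindingFreeEnergyResults`; the module-level functions expose
each pipeline stage individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import Frame, Selection, Topology, Trajectory, select
from .energetics import (
    EnergyComponents,
    GBParams,
    SasaParams,
    coulomb_energy,
    effective_born_radii,
    gb_cross_energy,
    gb_polar_energy,
    lj_energy,
    nonpolar_energy,
    sasa,
)

__all__ = [
    "BOLTZMANN_KCAL",
    "ThermoConstants",
    "EnthalpyResult",
    "EntropyResult",
    "FreeEnergySummary",
    "ResidueContribution",
    "AlanineScanResult",
    "binding_components_per_frame",
    "interaction_energy_series",
    "interaction_entropy",
    "combine_free_energy",
    "replica_average",
    "per_residue_decomposition",
    "call_hotspots",
    "mutate_to_alanine",
    "alanine_scan",
    "block_sem",
    "BindingFreeEnergy",
    "BindingFreeEnergyResults",
]

BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol*K)

#: beta*dE beyond which the exponential-average estimator is dominated
#: by a handful of frames and becomes unreliable
IE_DIAGNOSTIC_LIMIT = 25.0

HOTSPOT_THRESHOLD = -1.0  # kcal/mol, inclusive


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and derived thermal energy."""

    temperature: float = 300.0
    k_B: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT(self) -> float:
        return self.k_B * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


def block_sem(values: np.ndarray, n_blocks: int = 50) -> float:
    """Standard error of the mean by block averaging.

    Contiguous blocks blunt frame-to-frame autocorrelation; with fewer
    samples than requested blocks, each sample is its own block.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    n_blocks = max(1, min(n_blocks, n))
    if n_blocks < 2:
        return 0.0
    means = np.array([b.mean() for b in np.array_split(values, n_blocks)])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass(frozen=True)
class EnthalpyResult:
    """Frame-averaged MM/GBSA components and their block SEMs, kcal/mol.

    The identity dh == e_ele + e_vdw + g_gb + g_np holds exactly over
    the means.
    """

    e_ele: float
    e_vdw: float
    g_gb: float
    g_np: float
    sem_e_ele: float
    sem_e_vdw: float
    sem_g_gb: float
    sem_g_np: float
    sem_dh: float
    n_frames: int

    @property
    def dh(self) -> float:
        return self.e_ele + self.e_vdw + self.g_gb + self.g_np

    @classmethod
    def from_components(cls, components: Sequence[EnergyComponents],
                        n_blocks: int = 50) -> "EnthalpyResult":
        arr = {k: np.array([getattr(c, k) for c in components])
               for k in ("e_ele", "e_vdw", "g_gb", "g_np")}
        total = sum(arr.values())
        return cls(
            e_ele=float(arr["e_ele"].mean()),
            e_vdw=float(arr["e_vdw"].mean()),
            g_gb=float(arr["g_gb"].mean()),
            g_np=float(arr["g_np"].mean()),
            sem_e_ele=block_sem(arr["e_ele"], n_blocks),
            sem_e_vdw=block_sem(arr["e_vdw"], n_blocks),
            sem_g_gb=block_sem(arr["g_gb"], n_blocks),
            sem_g_np=block_sem(arr["g_np"], n_blocks),
            sem_dh=block_sem(total, n_blocks),
            n_frames=len(components),
        )


@dataclass(frozen=True)
class EntropyResult:
    """Interaction-entropy estimate −TΔS (≥ 0 by Jensen's inequality)
    with a block-bootstrap uncertainty and the max βΔE diagnostic."""

    minus_t_delta_s: float
    uncertainty: float
    max_beta_delta_e: float
    n_frames: int


@dataclass(frozen=True)
class FreeEnergySummary:
    """One table row: the seven reported columns with their errors."""

    e_vdw: float
    e_ele: float
    g_gb: float
    g_np: float
    dh: float
    minus_tds: float
    dg: float
    sem_e_vdw: float = 0.0
    sem_e_ele: float = 0.0
    sem_g_gb: float = 0.0
    sem_g_np: float = 0.0
    sem_dh: float = 0.0
    sem_minus_tds: float = 0.0
    sem_dg: float = 0.0
    label: str = ""

    COLUMNS = ("e_vdw", "e_ele", "g_gb", "g_np", "dh", "minus_tds", "dg")

    @classmethod
    def from_results(cls, enthalpy: EnthalpyResult, entropy: EntropyResult,
                     label: str = "") -> "FreeEnergySummary":
        dg = combine_free_energy(enthalpy.dh, entropy.minus_t_delta_s)
        sem_dg = float(np.hypot(enthalpy.sem_dh, entropy.uncertainty))
        return cls(
            e_vdw=enthalpy.e_vdw, e_ele=enthalpy.e_ele,
            g_gb=enthalpy.g_gb, g_np=enthalpy.g_np, dh=enthalpy.dh,
            minus_tds=entropy.minus_t_delta_s, dg=dg,
            sem_e_vdw=enthalpy.sem_e_vdw, sem_e_ele=enthalpy.sem_e_ele,
            sem_g_gb=enthalpy.sem_g_gb, sem_g_np=enthalpy.sem_g_np,
            sem_dh=enthalpy.sem_dh, sem_minus_tds=entropy.uncertainty,
            sem_dg=sem_dg, label=label,
        )


@dataclass(frozen=True)
class ResidueContribution:
    """Per-residue share of the binding free energy, kcal/mol."""

    residue_index: int
    residue_name: str
    ele: float
    vdw: float
    gb: float
    np_term: float
    hotspot: bool = False

    @property
    def contribution(self) -> float:
        return self.ele + self.vdw + self.gb + self.np_term


@dataclass(frozen=True)
class AlanineScanResult:
    """ASIE result for one residue: ΔΔG = ΔG^wild − ΔG^ala plus the
    mutant's enthalpy and entropy terms."""

    residue_index: int
    residue_name: str
    delta_delta_g: float
    wild_dg: float
    mutant_dg: float
    mutant_dh: float
    mutant_minus_tds: float


# ---------------------------------------------------------------------------
# stage 1: per-frame components

def binding_components_per_frame(
    topology: Topology,
    trajectory: Trajectory,
    gb: GBParams | None = None,
    sasa_params: SasaParams | None = None,
    charge_set: str = "default",
) -> list[EnergyComponents]:
    """Single-trajectory MM/GBSA components for every frame.

    Each ΔX is X(complex) − X(receptor) − X(ligand) with receptor and
    ligand coordinates taken from the complex frame, which reduces
    ΔE_ele and ΔE_vdW to the intermolecular pair sums.
    """
    gb = gb or GBParams()
    sasa_params = sasa_params or SasaParams()
    rec = select(topology, "segment:receptor")
    lig = select(topology, "segment:ligand")
    if not len(rec) or not len(lig):
        raise ValueError("topology must have nonempty receptor and ligand")
    all_sel = Selection(atom_indices=tuple(range(topology.n_atoms)),
                        label="complex")
    out = []
    for frame in trajectory.frames:
        e_ele = coulomb_energy(topology, frame, rec, lig, charge_set)
        e_vdw = lj_energy(topology, frame, rec, lig)
        g_gb = (
            gb_polar_energy(topology, frame, gb, all_sel, charge_set)
            - gb_polar_energy(topology, frame, gb, rec, charge_set)
            - gb_polar_energy(topology, frame, gb, lig, charge_set)
        )
        a_c = sasa(topology, frame, sasa_params, all_sel)
        a_r = sasa(topology, frame, sasa_params, rec)
        a_l = sasa(topology, frame, sasa_params, lig)
        delta_sasa = float(a_c.sum() - a_r.sum() - a_l.sum())
        out.append(EnergyComponents(
            e_ele=e_ele, e_vdw=e_vdw, g_gb=g_gb,
            g_np=nonpolar_energy(delta_sasa, sasa_params),
        ))
    return out


def interaction_energy_series(
    components: Sequence[EnergyComponents],
) -> np.ndarray:
    """Gas-phase receptor–ligand interaction energy per frame,
    E_pl^int = ΔE_ele + ΔE_vdW (the series entering the IE estimator)."""
    return np.array([c.e_ele + c.e_vdw for c in components])


# ---------------------------------------------------------------------------
# stage 2: interaction entropy

def interaction_entropy(
    series: np.ndarray,
    constants: ThermoConstants | None = None,
    n_blocks: int = 20,
    n_bootstrap: int = 100,
    bootstrap_seed: int = 0,
) -> EntropyResult:
    """Interaction-entropy estimate of the entropic penalty.

    −TΔS = kT·ln((1/n)Σ_i exp(β(E_i − Ē))), evaluated in shifted
    log-sum-exp form so the exponential average cannot overflow.  The
    uncertainty is a moving-block bootstrap over contiguous blocks of
    the series; ``max_beta_delta_e`` flags the regime (≳ 25) where the
    exponential average is dominated by a few frames.
    """
    constants = constants or ThermoConstants()
    values = np.asarray(series, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one energy sample")
    beta_dev = constants.beta * (values - values.mean())
    max_bde = float(beta_dev.max(initial=0.0))
    if max_bde > IE_DIAGNOSTIC_LIMIT:
        warnings.warn(
            f"max beta*dE = {max_bde:.1f} > {IE_DIAGNOSTIC_LIMIT:g}: "
            "interaction-entropy estimate dominated by rare frames",
            RuntimeWarning, stacklevel=2,
        )
    estimate = constants.kT * float(
        logsumexp(beta_dev) - np.log(values.size)
    )
    estimate = max(estimate, 0.0)  # clip numerical noise below Jensen bound

    uncertainty = 0.0
    n_blocks = max(1, min(n_blocks, values.size))
    if n_blocks >= 2 and n_bootstrap > 0:
        blocks = np.array_split(values, n_blocks)
        rng = np.random.default_rng(bootstrap_seed)
        replicates = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.integers(0, n_blocks, size=n_blocks)
            sample = np.concatenate([blocks[k] for k in pick])
            dev = constants.beta * (sample - sample.mean())
            replicates[b] = constants.kT * (
                logsumexp(dev) - np.log(sample.size)
            )
        uncertainty = float(replicates.std(ddof=1))
    return EntropyResult(
        minus_t_delta_s=estimate, uncertainty=uncertainty,
        max_beta_delta_e=max_bde, n_frames=values.size,
    )


def combine_free_energy(dh: float, minus_t_delta_s: float) -> float:
    """ΔG_bind = ΔH + (−TΔS)."""
    return dh + minus_t_delta_s


# ---------------------------------------------------------------------------
# stage 3: replica averaging

def replica_average(per_replica: Sequence[FreeEnergySummary],
                    label: str = "Average") -> FreeEnergySummary:
    """Column-wise mean across replicas.

    Values average arithmetically; the reported error of the average row
    is the mean of the per-replica SEMs (the convention used in
    published replica tables of this kind, where the Average-row errors
    are the means of the replica errors rather than the SEM of the
    replica means).
    """
    if not per_replica:
        raise ValueError("need at least one replica")
    kwargs = {}
    for col in FreeEnergySummary.COLUMNS:
        kwargs[col] = float(np.mean([getattr(r, col) for r in per_replica]))
        kwargs[f"sem_{col}"] = float(
            np.mean([getattr(r, f"sem_{col}") for r in per_replica])
        )
    return FreeEnergySummary(label=label, **kwargs)


# ---------------------------------------------------------------------------
# stage 4: per-residue decomposition and hot spots

def per_residue_decomposition(
    topology: Topology,
    trajectory: Trajectory,
    gb: GBParams | None = None,
    sasa_params: SasaParams | None = None,
    charge_set: str = "default",
    hotspot_threshold: float = HOTSPOT_THRESHOLD,
) -> list[ResidueContribution]:
    """Frame-averaged residue-wise shares of the binding free energy.

    For each receptor residue r: the Coulomb and LJ pair sums between r
    and the ligand (an exact partition of the intermolecular totals),
    the GB cross term between r and the ligand evaluated with complex
    effective radii, and γ times the residue's buried surface area
    (complex minus isolated receptor).
    """
    gb = gb or GBParams()
    sasa_params = sasa_params or SasaParams()
    rec = select(topology, "segment:receptor")
    lig = select(topology, "segment:ligand")
    if not len(lig):
        raise ValueError("topology has no ligand atoms")
    all_sel = Selection(atom_indices=tuple(range(topology.n_atoms)),
                        label="complex")
    residues = sorted({topology.atoms[i].residue_index
                       for i in rec.atom_indices})
    res_atoms = {r: np.array(topology.residue_atoms(r), dtype=int)
                 for r in residues}

    acc = {r: np.zeros(4) for r in residues}  # ele, vdw, gb, np
    for frame in trajectory.frames:
        radii_c = effective_born_radii(topology, frame, gb, all_sel)
        a_c = np.zeros(topology.n_atoms)
        a_r = np.zeros(topology.n_atoms)
        a_c[all_sel.indices] = sasa(topology, frame, sasa_params, all_sel)
        a_r[rec.indices] = sasa(topology, frame, sasa_params, rec)
        for r in residues:
            r_sel = Selection(atom_indices=tuple(res_atoms[r]),
                              label=f"res{r}")
            ele = coulomb_energy(topology, frame, r_sel, lig, charge_set)
            vdw = lj_energy(topology, frame, r_sel, lig)
            gbx = gb_cross_energy(topology, frame, gb, all_sel,
                                  res_atoms[r], lig.indices,
                                  charge_set, radii=radii_c)
            buried = float(np.sum(a_c[res_atoms[r]] - a_r[res_atoms[r]]))
            acc[r] += [ele, vdw, gbx, sasa_params.gamma * buried]

    n = trajectory.n_frames
    out = []
    for r in residues:
        ele, vdw, gbx, np_term = acc[r] / n
        contrib = ele + vdw + gbx + np_term
        out.append(ResidueContribution(
            residue_index=r, residue_name=topology.residue_name(r),
            ele=ele, vdw=vdw, gb=gbx, np_term=np_term,
            hotspot=contrib <= hotspot_threshold,
        ))
    return out


def call_hotspots(contributions: Sequence[ResidueContribution],
                  threshold: float = HOTSPOT_THRESHOLD) -> list[int]:
    """Residues whose contribution is at least as favorable as the
    threshold (≤ −1 kcal/mol by default, boundary inclusive), sorted
    most-favorable first."""
    hits = [c for c in contributions if c.contribution <= threshold]
    hits.sort(key=lambda c: (c.contribution, c.residue_index))
    return [c.residue_index for c in hits]


# ---------------------------------------------------------------------------
# stage 5: alanine scanning

_BACKBONE_KEEP = frozenset({"N", "H", "HN", "CA", "HA", "C", "O", "OXT"})
_GAMMA_NAMES = ("CG", "CG1", "CG2", "OG", "OG1", "SG")

# alanine side-chain parameters: CB and the hydrogen replacing the
# gamma heavy atom
_ALA_CB = dict(charge=-0.1825, lj_rmin_half=1.9080, lj_epsilon=0.1094,
               gb_radius=1.70, gb_screen=0.72, mass=12.011)
_ALA_HB = dict(charge=0.0603, lj_rmin_half=1.4870, lj_epsilon=0.0157,
               gb_radius=1.20, gb_screen=0.85, mass=1.008)

_CH_BOND = 1.09  # Angstrom, aliphatic C-H


def mutate_to_alanine(
    topology: Topology, trajectory: Trajectory, residue_index: int,
) -> tuple[Topology, Trajectory]:
    """Truncate one receptor residue to alanine on every frame.

    Side-chain atoms beyond Cβ are removed; Cβ takes alanine
    parameters; the former gamma heavy atom becomes a hydrogen placed at
    1.09 Å from Cβ along the old Cβ–gamma direction.  Mutating an
    alanine is the identity (same objects returned); GLY and PRO are
    rejected.
    """
    res_atoms = topology.residue_atoms(residue_index)
    if not res_atoms:
        raise ValueError(f"no residue {residue_index}")
    res_name = topology.atoms[res_atoms[0]].residue_name
    if topology.atoms[res_atoms[0]].segment != "receptor":
        raise ValueError("can only mutate receptor residues")
    if res_name in ("GLY", "PRO"):
        raise ValueError(f"cannot mutate {res_name} to alanine")
    if res_name == "ALA":
        return topology, trajectory

    names = {topology.atoms[i].name: i for i in res_atoms}
    if "CB" not in names:
        raise ValueError(f"residue {residue_index} has no CB atom")
    cb_idx = names["CB"]
    gamma_idx = next((names[n] for n in _GAMMA_NAMES if n in names), None)
    if gamma_idx is None:
        raise ValueError(
            f"residue {residue_index} ({res_name}) has no gamma heavy atom"
        )

    keep: list[int] = []
    for a in topology.atoms:
        if a.residue_index != residue_index:
            keep.append(a.index)
        elif a.name in _BACKBONE_KEEP or a.index == cb_idx \
                or a.index == gamma_idx or a.name.startswith("HB"):
            keep.append(a.index)
    keep.sort()
    old_to_new = {old: new for new, old in enumerate(keep)}

    new_atoms = []
    override: dict[int, dict] = {
        cb_idx: dict(name="CB", element="C", **_ALA_CB),
        gamma_idx: dict(name="HB3", element="H", **_ALA_HB),
    }
    for old in keep:
        a = topology.atoms[old]
        fields = dict(
            name=a.name, element=a.element, residue_index=a.residue_index,
            residue_name=a.residue_name, segment=a.segment, charge=a.charge,
            lj_rmin_half=a.lj_rmin_half, lj_epsilon=a.lj_epsilon,
            gb_radius=a.gb_radius, gb_screen=a.gb_screen, mass=a.mass,
        )
        if a.residue_index == residue_index:
            fields["residue_name"] = "ALA"
        if old in override:
            fields.update(override[old])
        new_atoms.append(type(a)(index=old_to_new[old], **fields))

    keep_arr = np.array(keep, dtype=int)
    new_sets = {}
    for name, vec in topology.charge_sets.items():
        v = vec[keep_arr].copy()
        v[old_to_new[cb_idx]] = _ALA_CB["charge"]
        v[old_to_new[gamma_idx]] = _ALA_HB["charge"]
        new_sets[name] = v
    new_top = Topology(atoms=tuple(new_atoms), charge_sets=new_sets)

    new_frames = []
    for frame in trajectory.frames:
        coords = frame.coordinates[keep_arr].copy()
        cb = frame.coordinates[cb_idx]
        gam = frame.coordinates[gamma_idx]
        direction = gam - cb
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            raise ValueError("degenerate CB-gamma geometry")
        coords[old_to_new[gamma_idx]] = cb + _CH_BOND * direction / norm
        new_frames.append(Frame(coordinates=coords))
    new_traj = replace(trajectory, frames=tuple(new_frames),
                       source=trajectory.source + f"|ala{residue_index}")
    return new_top, new_traj


def _single_point(topology, trajectory, gb, sasa_params, constants,
                  charge_set, n_blocks):
    comps = binding_components_per_frame(
        topology, trajectory, gb, sasa_params, charge_set)
    enthalpy = EnthalpyResult.from_components(comps, n_blocks)
    entropy = interaction_entropy(
        interaction_energy_series(comps), constants)
    return FreeEnergySummary.from_results(enthalpy, entropy)


def alanine_scan(
    topology: Topology,
    trajectory: Trajectory,
    residues: Sequence[int],
    gb: GBParams | None = None,
    sasa_params: SasaParams | None = None,
    constants: ThermoConstants | None = None,
    charge_set: str = "default",
    n_blocks: int = 50,
) -> list[AlanineScanResult]:
    """ASIE over a residue list on shared wild-type frames.

    For each residue the mutant ΔH (MM/GBSA) and −TΔS (IE) are
    recomputed on the same frames and ΔΔG = ΔG^wild − ΔG^ala reported.
    Residues that cannot be mutated are skipped with a warning.
    """
    gb = gb or GBParams()
    sasa_params = sasa_params or SasaParams()
    constants = constants or ThermoConstants()
    wild = _single_point(topology, trajectory, gb, sasa_params, constants,
                         charge_set, n_blocks)
    out = []
    for r in residues:
        try:
            mut_top, mut_traj = mutate_to_alanine(topology, trajectory, r)
        except ValueError as exc:
            warnings.warn(f"skipping residue {r}: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        if mut_top is topology:  # identity mutation (already alanine)
            mutant = wild
        else:
            mutant = _single_point(mut_top, mut_traj, gb, sasa_params,
                                   constants, charge_set, n_blocks)
        out.append(AlanineScanResult(
            residue_index=r, residue_name=topology.residue_name(r),
            delta_delta_g=wild.dg - mutant.dg,
            wild_dg=wild.dg, mutant_dg=mutant.dg,
            mutant_dh=mutant.dh, mutant_minus_tds=mutant.minus_tds,
        ))
    return out


# ---------------------------------------------------------------------------
# model / results facade

class BindingFreeEnergy:
    """End-point binding free energy model over replica trajectories.

    Parameters
    ----------
    topology : Topology
        Parameterized complex with receptor/ligand partition.
    replicas : sequence of Trajectory
        One complex trajectory per independent replica.
    charge_set : str
        Named charge vector to use (e.g. ``"default"`` or ``"ppc"``).
    temperature : float
        Kelvin; sets kT for the entropy estimator.
    window : "last_half" | None | (start, stop, stride)
        Frame window applied to each replica before analysis.  The
        default keeps the last half of each replica, the usual
        equilibrated-production convention.
    """

    def __init__(self, topology: Topology, replicas: Sequence[Trajectory],
                 *, charge_set: str = "default", temperature: float = 300.0,
                 gb_params: GBParams | None = None,
                 sasa_params: SasaParams | None = None,
                 window: str | tuple | None = "last_half",
                 n_blocks: int = 50):
        self.topology = topology
        self.replicas = list(replicas)
        if not self.replicas:
            raise ValueError("need at least one replica trajectory")
        self.charge_set = charge_set
        self.constants = ThermoConstants(temperature=temperature)
        self.gb_params = gb_params or GBParams()
        self.sasa_params = sasa_params or SasaParams()
        self.window = window
        self.n_blocks = n_blocks

    def _windowed(self, traj: Trajectory) -> Trajectory:
        if self.window is None:
            return traj
        if self.window == "last_half":
            return traj.window(start=traj.n_frames // 2)
        start, stop, stride = self.window
        return traj.window(start=start, stop=stop, stride=stride or 1)

    def fit(self) -> "BindingFreeEnergyResults":
        """Run MM/GBSA + IE on every replica and average."""
        rows = []
        for i, traj in enumerate(self.replicas):
            w = self._windowed(traj)
            comps = binding_components_per_frame(
                self.topology, w, self.gb_params, self.sasa_params,
                self.charge_set)
            enthalpy = EnthalpyResult.from_components(comps, self.n_blocks)
            entropy = interaction_entropy(
                interaction_energy_series(comps), self.constants)
            label = f"No. {traj.replica_id or i + 1}"
            rows.append(FreeEnergySummary.from_results(
                enthalpy, entropy, label=label))
        return BindingFreeEnergyResults(self, rows, replica_average(rows))

    def decompose(self, hotspot_threshold: float = HOTSPOT_THRESHOLD,
                  ) -> list[ResidueContribution]:
        """Per-residue decomposition averaged over replicas' frames."""
        per_rep = []
        for traj in self.replicas:
            per_rep.append(per_residue_decomposition(
                self.topology, self._windowed(traj), self.gb_params,
                self.sasa_params, self.charge_set, hotspot_threshold))
        merged = []
        for items in zip(*per_rep):
            first = items[0]
            ele = float(np.mean([c.ele for c in items]))
            vdw = float(np.mean([c.vdw for c in items]))
            gbx = float(np.mean([c.gb for c in items]))
            np_t = float(np.mean([c.np_term for c in items]))
            merged.append(ResidueContribution(
                residue_index=first.residue_index,
                residue_name=first.residue_name,
                ele=ele, vdw=vdw, gb=gbx, np_term=np_t,
                hotspot=(ele + vdw + gbx + np_t) <= hotspot_threshold,
            ))
        return merged

    def alanine_scan(self, residues: Sequence[int]
                     ) -> list[AlanineScanResult]:
        """ASIE averaged over replicas (ΔΔG means across replicas)."""
        per_rep = [
            alanine_scan(self.topology, self._windowed(traj), residues,
                         self.gb_params, self.sasa_params, self.constants,
                         self.charge_set, self.n_blocks)
            for traj in self.replicas
        ]
        merged = []
        for items in zip(*per_rep):
            first = items[0]
            merged.append(AlanineScanResult(
                residue_index=first.residue_index,
                residue_name=first.residue_name,
                delta_delta_g=float(np.mean(
                    [x.delta_delta_g for x in items])),
                wild_dg=float(np.mean([x.wild_dg for x in items])),
                mutant_dg=float(np.mean([x.mutant_dg for x in items])),
                mutant_dh=float(np.mean([x.mutant_dh for x in items])),
                mutant_minus_tds=float(np.mean(
                    [x.mutant_minus_tds for x in items])),
            ))
        return merged


class BindingFreeEnergyResults:
    """Fitted binding free energy: per-replica rows plus the average."""

    def __init__(self, model: BindingFreeEnergy,
                 replica_rows: list[FreeEnergySummary],
                 average: FreeEnergySummary):
        self.model = model
        self.replica_rows = replica_rows
        self.average = average

    @property
    def dg_bind(self) -> float:
        return self.average.dg

    @property
    def dh(self) -> float:
        return self.average.dh

    @property
    def minus_tds(self) -> float:
        return self.average.minus_tds

    def to_frame(self) -> pd.DataFrame:
        """Replica rows and average as a DataFrame (full precision)."""
        rows = self.replica_rows + [self.average]
        data = {"row": [r.label or f"No. {i + 1}"
                        for i, r in enumerate(rows)]}
        for col in FreeEnergySummary.COLUMNS:
            data[col] = [getattr(r, col) for r in rows]
            data[f"sem_{col}"] = [getattr(r, f"sem_{col}") for r in rows]
        return pd.DataFrame(data)

    def summary(self) -> str:
        """Human-readable table (two decimals, mean ± SEM, kcal/mol)."""
        from .reporting import render_summary_table
        return render_summary_table(self.replica_rows, self.average)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<BindingFreeEnergyResults dG={self.dg_bind:.2f} "
                f"dH={self.dh:.2f} -TdS={self.minus_tds:.2f} kcal/mol, "
                f"{len(self.replica_rows)} replica(s)>")
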
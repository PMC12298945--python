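# gbind

End-point binding free energy analysis of molecular-dynamics
trajectories: MM/GBSA enthalpies, the interaction-entropy estimator of
the entropic penalty, per-residue decomposition with hot-spot calling,
alanine-scanning interaction entropy (ASIE), and the standard
structural-dynamics toolbox (RMSD/RMSF, hydrogen-bond occupancy, DCCM,
PCA, conformational clustering).

It is written for computational chemists who post-process protein–ligand
complex trajectories — for example PCSK9–inhibitor systems, where the
flat protein–protein-interaction surface makes careful free-energy
bookkeeping across replicas and charge models (additive force-field
charges versus polarized protein-specific charges, PPC) essential.

## The model

The binding free energy is assembled as

    ΔG_bind = ΔH + (−TΔS)

**Enthalpy (MM/GBSA, single-trajectory protocol).** For every frame of
the complex trajectory, receptor and ligand conformations are extracted
from the complex, so intramolecular gas-phase terms cancel and

    ΔH = ΔE_ele + ΔE_vdW + ΔG_gb + ΔG_np

with intermolecular Coulomb (k_e = 332.0637 kcal·Å/mol·e², no cutoff)
and 12-6 Lennard-Jones sums, OBC-II Generalized Born polar solvation
(ε_in = 1, ε_out = 78.5), and a linear nonpolar term
ΔG_np = γ·ΔSASA + β with γ = 0.0072 kcal/mol/Å², β = 0 over
Shrake–Rupley surface areas. Means and block-averaged SEMs are reported
per replica; the cross-replica Average row takes the mean of values and
the mean of per-replica SEMs.

**Entropy (interaction entropy).** From the per-frame gas-phase
interaction energy E_int = ΔE_ele + ΔE_vdW,

    −TΔS = kT · ln ⟨ exp(β (E_int − ⟨E_int⟩)) ⟩,   β = 1/kT,

evaluated in shifted log-sum-exp form (it is ≥ 0 by Jensen's
inequality) with a moving-block-bootstrap uncertainty and a max βΔE
diagnostic for the regime where the exponential average becomes
unreliable.

**Decomposition and ASIE.** Each receptor residue's share of the
binding free energy is its Coulomb/LJ pair sums with the ligand, its GB
cross term under complex effective radii, and γ times its buried
surface; residues at or below −1 kcal/mol are hot spots. Alanine
scanning truncates a residue beyond Cβ on the wild-type frames,
recomputes both ΔH and −TΔS, and reports ΔΔG = ΔG^wild − ΔG^ala
(hot spots come out negative under this sign convention).

Because real MD trajectories are too heavy for tests, a seeded
synthetic module generates toy receptor–ligand complexes with planted
hydrogen bonds, Gaussian coordinate ensembles with prescribed
covariance, and energy series with known distributions — every
estimator can therefore be checked against closed forms.

## Worked example

```python
import numpy as np
from gbind import (BindingFreeEnergy, EnsembleSpec, ToyComplexSpec,
                   build_toy_complex, generate_ensemble, hbond_occupancy)

top, frame = build_toy_complex(ToyComplexSpec(
    n_receptor_residues=8, ligand_atoms=6, hbond_pairs=((6, 0),), seed=1))
replicas = [generate_ensemble(EnsembleSpec(
    reference=frame, covariance=0.04**2 * np.eye(3 * top.n_atoms),
    n_frames=100, seed=s), top) for s in (1, 2, 3)]

result = BindingFreeEnergy(top, replicas, temperature=300.0).fit()
print(result.summary())
```

prints (kcal/mol, mean ± SEM):

```
Replica dE_vdw       dE_ele       dG_gb         dG_np         dH            -TdS         dG_bind
No. 1   0.09 ± 0.05  1.51 ± 0.09  -3.14 ± 0.06  -0.72 ± 0.00  -2.26 ± 0.05  0.48 ± 0.07  -1.79 ± 0.09
No. 2   0.05 ± 0.05  1.45 ± 0.11  -3.08 ± 0.07  -0.72 ± 0.00  -2.30 ± 0.05  0.54 ± 0.09  -1.75 ± 0.10
No. 3   0.04 ± 0.05  1.62 ± 0.10  -3.18 ± 0.06  -0.72 ± 0.00  -2.24 ± 0.05  0.46 ± 0.08  -1.78 ± 0.09
Average 0.06 ± 0.05  1.53 ± 0.10  -3.14 ± 0.06  -0.72 ± 0.00  -2.27 ± 0.05  0.49 ± 0.08  -1.77 ± 0.09
```

The planted hydrogen bond dominates the interface: desolvation
(ΔG_gb = −3.14) outweighs the slightly repulsive gas-phase contact
terms, the entropic penalty is small, and the complex binds with
ΔG_bind ≈ −1.8 kcal/mol. Scanning the donor residue confirms it is the
hot spot:

```python
scan = BindingFreeEnergy(top, replicas[:1], window=None).alanine_scan([6])
print(f"ddG(SER6 -> ALA) = {scan[0].delta_delta_g:+.2f} kcal/mol")
# ddG(SER6 -> ALA) = -0.56 kcal/mol   (wild type binds better)
bonds = hbond_occupancy(top, replicas[0])
print(bonds[0].label, bonds[0].occupancy)   # SER6:OG->LIG8:O1 1.0
```

The same pipeline is scriptable from the shell (`gbind simulate`,
`gbind gbsa`, `gbind asie`, `gbind decompose`, `gbind rmsf`,
`gbind dccm`, `gbind pca`, `gbind cluster`, `gbind report`, ...); every
command writes a full-precision JSON twin of its table along with the
resolved configuration and seed.

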
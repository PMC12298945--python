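# Methods

This note records the models implemented in `gbind`, the numerical
choices behind them, and what the synthetic generators do and do not
emulate.

## End-point free energy model

The package computes `ΔG_bind = ΔH + (−TΔS)` from a complex trajectory
under the **single-trajectory protocol**: receptor and ligand
conformations are sliced out of each complex frame rather than sampled
separately. Intramolecular bonded and nonbonded terms then cancel in
every ΔX = X(complex) − X(receptor) − X(ligand) difference, so the
gas-phase terms reduce to intermolecular pair sums and no
bond/angle/dihedral parameters are needed anywhere in the pipeline.
This is the common default for end-point analyses; its known cost is
that it ignores binding-induced conformational reorganization.

### Gas-phase terms

* Coulomb: `k_e Σ q_i q_j / r_ij` over receptor×ligand pairs with
  `k_e = 332.0637 kcal·Å/(mol·e²)` and no distance cutoff (end-point
  post-processing convention; the simulation engine's PME cutoff is out
  of scope here). Coincident atoms (r < 1e−6 Å) raise.
* Lennard-Jones 12-6 in the r_min/ε parameterization with
  `r_min,ij = r_min,i/2 + r_min,j/2`, `ε_ij = √(ε_i ε_j)`, so a pair at
  exactly r_min contributes −ε_ij.

Charges come from a **named charge set** on the topology. A topology
carries any number of per-atom charge vectors (e.g. `"default"` for
additive force-field charges and `"ppc"` for polarized
protein-specific charges); switching sets changes only the
electrostatics, which makes additive-versus-polarized comparisons a
one-flag rerun of the same trajectory.

### Polar solvation (Generalized Born)

The GB flavor is OBC-II. Intrinsic radii ρ are reduced by
`radius_offset = 0.09 Å`; pairwise HCT descreening integrals accumulate
into Ψ; and the effective radius follows
`1/R_i = 1/(ρ_i−δ) − tanh(αΨ − βΨ² + γΨ³)/ρ_i` with
(α, β, γ) = (1.0, 0.8, 4.85). An isolated atom recovers R = ρ − δ
exactly, which anchors the Born-ion closed-form test. The energy is the
full double sum `−(k_e/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB` with
`f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j))` and self terms `f_GB = R_i`;
defaults ε_in = 1, ε_out = 78.5. The OBC constants are configurable so
other GB variants of the same family can be expressed; no
Poisson–Boltzmann solver is provided.

### Nonpolar solvation

`ΔG_np = γ·ΔSASA + β` with γ = 0.0072 kcal/mol/Å², β = 0. SASA is
Shrake–Rupley quadrature on a deterministic golden-spiral point set
(default 960 points per sphere, probe 1.4 Å, atomic radii defaulting to
the intrinsic Born radii). 960 points keep an isolated sphere within 1%
of 4π(r+probe)² while staying cheap; the point set is fixed, so results
are bit-reproducible. ΔSASA for binding uses the same parameters for
complex, receptor, and ligand.

### Interaction entropy

`−TΔS = kT ln⟨exp(βΔE_int)⟩` with ΔE_int the fluctuation of the
gas-phase interaction energy about its mean, computed via a shifted
log-sum-exp (overflow-free by construction) and clipped at zero, the
Jensen bound. Two numerical policies matter:

* **Uncertainty** is a moving-block bootstrap (20 contiguous blocks,
  100 resamples, fixed internal seed) rather than a naive SEM — the
  estimator is a nonlinear functional of the sample and its error is
  not the error of a mean.
* **Diagnostic**: when `max β(E_i − Ē)` exceeds 25, a handful of frames
  dominates the exponential average and the estimate is flagged with a
  warning; the value is still reported. The estimator's finite-sample
  bias is negative (ln of a sample mean) and vanishes as n grows; the
  test suite checks the σ²/2kT Gaussian limit and the monotone decay
  of the bias across n ∈ {10³, 10⁴, 10⁶}.

### Replica bookkeeping

Per replica, component means carry block-averaged SEMs (50 blocks by
default; blocks blunt frame autocorrelation). The cross-replica Average
row is the arithmetic mean of values and **the mean of the per-replica
SEMs** — the convention used by the published replica tables this
package mirrors (verifiable on those rows), not the SEM of the replica
means. ΔH = ΔE_ele + ΔE_vdW + ΔG_gb + ΔG_np and ΔG = ΔH + (−TΔS) hold
exactly at replica and average level. The default analysis window is
the last half of each replica (the usual equilibrated-production
choice); start/stop/stride are configurable.

### Decomposition and hot spots

Residue r's contribution is
`ele(r↔ligand) + vdW(r↔ligand) + GB_cross(r↔ligand) + γ·ΔSASA_r`,
frame-averaged. The Coulomb and LJ parts partition the intermolecular
totals exactly (asserted at 1e−8 relative); the GB cross term is
evaluated with complex effective radii, and ΔSASA_r is the residue's
buried area (complex minus isolated receptor). Residues with
contribution ≤ −1.0 kcal/mol (boundary inclusive — "exceeding −1" is
read as at-least-as-favorable) are hot spots, returned most-favorable
first.

### Alanine scanning (ASIE)

Single-trajectory alanine scanning on wild-type frames: side-chain
atoms beyond Cβ are removed, Cβ takes alanine parameters, and the
former γ-heavy atom becomes a hydrogen at 1.09 Å along the old Cβ–γ
direction in every frame. Both ΔH and −TΔS are recomputed for the
mutant, and `ΔΔG = ΔG^wild − ΔG^ala` — under this sign convention a
residue whose wild-type side chain stabilizes binding scores negative.
GLY and PRO are rejected (no Cβ / ring backbone); mutating an alanine
is the exact identity. When a residue list contains an unmutable
residue it is skipped with a warning rather than aborting the scan.

## Structural dynamics layer

* **Superposition**: Kabsch SVD fit returning a proper rotation
  (det = +1 enforced by sign correction); collinear or <3-atom
  selections are rejected as degenerate. RMSD series re-fit every frame
  to the reference.
* **RMSF**: two-pass alignment (fit to first frame, recompute the mean
  structure, re-fit to it) before measuring per-atom fluctuations;
  atoms are averaged within residues and replicas contribute a mean ±
  standard-error profile. The reference is configurable; an
  `align=False` path serves pre-aligned (e.g. synthetic) ensembles.
* **Hydrogen bonds**: geometric criterion, donor–acceptor heavy
  distance ≤ 3.5 Å and D–H···A angle ≥ 135° (configurable; the
  criterion is a package choice since conventions vary). Hydrogens are
  resolved per frame by a 1.3 Å covalent cutoff from the donor.
  Occupancy is the counting fraction of frames, pairs ranked by
  occupancy.
* **DCCM**: `C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩)` over pooled aligned
  frames; the diagonal is exactly 1, zero-variance atoms get zeroed
  off-diagonals with a warning (the ratio is undefined).
* **PCA**: eigendecomposition of the 3m×3m Cartesian covariance of the
  selected atoms, eigenvalues clipped at zero, variance fractions over
  the full spectrum, per-frame projections onto the leading components.
* **Clustering**: K-means (scikit-learn, k-means++ seeding, fixed
  random state) on flattened aligned coordinates, where Euclidean
  distance approximates pairwise RMSD. Labels are canonicalized by
  descending population; each cluster's representative is the member
  frame nearest its centroid, lowest index on ties. k is a user choice
  (default 3) — the inertia is reported to help judge it.

Selections are named (`heavy_all`, `heavy_paper`, `calpha`, `backbone`,
segment and residue-range selectors). `heavy_paper` restricts heavy
atoms to C/N/O — a narrow literal convention some reports use —
while `heavy_all` (every non-hydrogen) is the recommended default;
both exist so either convention is reproducible.

## Synthetic data: what it emulates and what it does not

The generators produce (a) multivariate-normal coordinate ensembles
about a reference with an arbitrary prescribed covariance (optionally
AR(1)-correlated in time, marginals preserved), (b) i.i.d. energy
series from Gaussian/two-point/mixture laws, and (c) toy
receptor–ligand complexes: an extended zig-zag strand of simplified
residues (N/CA/C/O backbone, Cβ–Cγ stub side chains, serine-like
hydroxyls on request) with a compact neutral ligand whose acceptor
oxygens sit at planted hydrogen-bond geometries (D···A 2.85 Å, linear
D–H···A) backed by carbonyl-like partner carbons, Amber-flavoured
parameters throughout, and a global 1.0 Å minimum separation. All
generators are pure functions of their spec including the seed.

Every in-scope estimator is a functional of the empirical distribution
over frames, so i.i.d. frames exercise all of them with known ground
truth. What i.i.d. frames do **not** emulate is the collective,
spatially correlated motion of real MD: independent per-atom jitter
feeds directly into relative contact distances, whereas in real
trajectories bonded neighbors move together. The energy-analysis
ensembles therefore use a small jitter (σ = 0.04 Å per coordinate,
300 frames for scanning runs) — enough to exercise the fluctuation
estimators, small enough that the 1.8 Å hydrogen-bond contact does not
sample the Lennard-Jones wall, which would be a pure artifact of the
i.i.d. construction. Consequently, passing tests demonstrate correct
estimator mathematics and bookkeeping, not force-field realism; the
dynamics-recovery tests plant their structure (correlations, spectra,
cluster weights) directly in the covariance, where alignment-free
recovery is exact in expectation.

A small reference table of published replica-level MM/GBSA + IE
summaries for three PCSK9–inhibitor complexes under two charge models
ships in `gbind.datasets`; it exercises the replica-averaging
conventions on real printed rows (their Average-row errors are means
of replica errors, which fixed that convention here).

## Degenerate inputs and tie-breaks

Zero-length selections, overlapping energy selections, empty frame
windows, non-PSD covariances, k > n_frames, donors without hydrogens,
and sub-micro-Å pair distances all raise (or warn-and-skip where a
batch should survive one bad item). Ties anywhere resolve to the
lowest frame index. Trajectory round-trips through multi-model PDB are
exact to the format's fixed 3-decimal precision; the JSON topology
round-trip is byte-identical in canonical form.

## Known limitations

* Single-trajectory protocol only; no separate receptor/ligand
  simulations, hence no reorganization energy.
* No normal-mode or quasi-harmonic entropy; IE only.
* GB is OBC-II with configurable constants; no PB solver, no salt
  (Debye–Hückel) term.
* The GB cross-term attribution in per-residue decomposition (complex
  radii) is one of several defensible conventions; only the Coulomb/LJ
  parts partition exactly.
* The toy complex is a geometric construction with plausible
  parameters, not a parameterized molecule; absolute toy energies mean
  nothing outside the test contrasts they were designed for.
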
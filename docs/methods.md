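# Methods

This note documents the models, estimators, conventions and numerical
choices implemented in `switchscan`, and what the synthetic fixtures do and
do not establish about behaviour on real trajectories.

## Containers and conventions

Structures are parsed from PDB with MDAnalysis; every ATOM/HETATM record
becomes one atom, re-indexed 0..n−1 regardless of the file's serial numbers.
Residue numbering is kept verbatim from the file (1-based), so residues of
interest (12, 32, 34, 35, 60, 61 in the 5P21 numbering of HRAS) are
addressed by their printed number, never by sequence index. Atom-name
dialects are normalised through a configurable synonym table (Tyr side-chain
oxygen `OH`; backbone amide proton `HN` or `H`; GTP γ-phosphate `PG` or
`P3`; Thr `OG1` or `OG`).

Trajectories (DCD, XTC, multi-model PDB) load into a frames × atoms × 3
array with per-frame replicate provenance; one file is one replicate.
Superposition is a Kabsch least-squares fit of a selection to a fixed
reference — the first frame by default, overridable — applied rigidly to the
whole frame. A single fixed reference rather than iterative mean-structure
fitting keeps the operation linear and reproducible; the choice of reference
frame only shifts the common frame of all structures, not any internal
coordinate. Superposition preserves all intra-frame distances to machine
precision (asserted by tests).

## Descriptors

**RMSF.** Within each replicate, each selected atom's mean-square deviation
from its time-mean position is averaged over frames; a residue's RMSF is the
root of the mean of its selected atoms' MSFs, and the profile reports the
mean ± standard error across replicates. Aggregating atomic MSFs before the
root (rather than averaging atomic RMSFs) makes the per-residue value the
fluctuation amplitude of the residue treated as a rigid group; the
difference from the alternative convention is second order. For isotropic
Gaussian displacements of width σ per coordinate the estimator converges to
σ√3, which the tests verify against generated ensembles.

**Standard errors.** Quantities averaged across replicates (RMSF, histogram
densities) use the across-replicate SE. Time-averaged scalars from a pooled
trajectory (hydration counts, distance means) use a block-averaged SE of the
mean with 5 contiguous blocks, the standard remedy for autocorrelated
samples; with fewer samples than blocks the SE degrades to 0 rather than to
a misleadingly small i.i.d. value.

**Histograms.** Probability densities are normalized so Σ density·width = 1
exactly. Distance bins sit on a grid anchored at 0 (1 Å default width);
angle histograms wrap onto (−180°, 180°] with 20° bins anchored at −180°, so
peaks near ±90° fall inside bins rather than on seams. Dihedrals follow the
IUPAC sign convention (cis = 0°), computed by MDAnalysis; the Tyr χ₂
quadruple defaults to Cα–Cβ–Cγ–Cδ1 and is overridable.

**Hydration.** A water molecule counts once per frame if any of its selected
atoms lies strictly within the cutoff (default 5 Å) of any solute atom;
exactly-at-cutoff is excluded. Counting molecules, not atoms, matches the
magnitude (~70–100) of nucleotide-pocket hydration numbers. Neighbour search
uses a k-d tree per frame.

## Collective motion

The covariance C = ⟨Δr Δrᵀ⟩ is taken over pooled frames with deviations from
the pooled time-mean structure and population normalisation 1/T. Weighting
is unit by default — matching the common `gmx covar` convention without mass
flags — with mass weighting available as an option, since the literature is
not unanimous on the weighting entering the covariance.

Eigendecomposition uses a dense symmetric solver; eigenvalues are sorted
descending and each eigenvector's sign is fixed so its largest-magnitude
component is positive, which makes results reproducible up to genuine
degeneracy (degenerate subspaces are compared as subspaces in tests).
Projections of the centered trajectory on mode m have variance exactly λ_m
under the 1/T convention, and the mode-subspace reconstruction underlying
the eigen-RMSF recovers the plain RMSF when all 3N modes are included — both
are asserted at 1e-8 as exactness properties, not statistical checks.

## State classification

Switch I is labelled from the Cα(12)–Cα(34) distance: closed strictly below
8 Å, open strictly above 16 Å, partially open on [8, 16]. Switch II is open
strictly above 11 Å and closed otherwise, so 11.0 Å is closed. The boundary
assignments are forced by the worked-example labels the rules must
reproduce (a distance printed as 11.00 Å labelled closed). Classification
is total and monotone in distance (property-tested).

The most probable conformation is located on a 2-D histogram of two distance
coordinates (default T35 Oγ–GTP Pγ vs G60 HN–GTP Pγ, 1 Å bins anchored
at 0); ties between equally occupied bins break to the lexicographically
smallest bin index, and the representative frame is the one nearest the
modal bin center in the two-distance plane (ties to the lowest frame
index). The three literature sub-state ranges for the T35 and G60
coordinates are shipped as a descriptive preset (`CLUSTER_STATE_PRESET`) but
play no role in the classification rules. Two coordinate-pair conventions
coexist in the source analyses (T35-based for clustering, Cα12–Cα34-based
for state definitions); both are supported and the defaults are documented
per function rather than reconciled.

## Perturbation-response scanning

Linear response on the Cα network predicts the displacement under a point
force as ΔR = (1/k_BT) C ΔF, with C the displacement covariance of an
equilibrated chunk (the final 50% of frames by default, overridable) and
k_BT = 0.616 kcal/mol at the default 310 K. The scan applies n random unit
forces (default 1000, normalized Gaussian triples — uniform on the sphere)
to each node's three components in turn, scores each response against the
target displacement ΔS by the signed cosine overlap, and keeps each node's
signed maximum; residues are ranked by best overlap. Force magnitude is
immaterial: the overlap is invariant under positive rescaling (asserted
numerically). ΔS is computed after superposing the target structure onto
the initial one on all Cα, so rigid-body motion does not masquerade as
deformation.

A dense cross-check solves each node's optimal direction analytically (the
3×3 problem maximizing cos(B_i f, ΔS) over unit f has maximizer
f* ∝ (B_iᵀB_i)⁻¹B_iᵀΔS); the stochastic ranking must agree with the dense
one at Spearman ρ ≥ 0.95 and can never exceed it node-wise. At 1000
directions the per-node best overlap is saturated to within 0.02 across
seeds.

The winning residue/direction exports to a pulling specification carrying
the reference protocol defaults: pull the Cα at 0.03 Å/ps with a
90 kcal mol⁻¹ Å⁻² spring, anchor residues 23 and 149 fixed.

## PMF from pulling work

Work is accumulated per run by trapezoidal integration of the projected
spring force against the *scheduled* coordinate v·t — the coordinate the
external constraint actually moves along in constant-velocity pulling —
while the profile is *binned* by the pulled atom's projected displacement
(0.4 Å bins anchored at 0, covering the range every retained run reaches).
A run's work at a bin is the mean of its work samples recorded while its
displacement lay in that bin. This bin-average is the symmetric, unbiased
reading of "binning the displacement vs force data"; taking instead the work
at first passage of the bin rides a favorable thermal kick and is
systematically low by roughly force × fluctuation-width, a bias that grows
wherever the potential is steep (verified on the harmonic fixture, where
bin-averaging recovers the analytic profile to ~0.05 kcal/mol and
first-passage interpolation misses by ~0.7).

The estimate per bin is the second-order cumulant
F = ⟨W⟩ − (⟨W²⟩ − ⟨W⟩²)/(2k_BT) with population moments (the literal second
cumulant), referenced to zero at the first occupied bin. It is bounded above
by ⟨W⟩ and exact for Gaussian work; the full Jarzynski exponential average
is implemented as an internal cross-check only, since at ~70 runs its bias
exceeds the cumulant's for near-Gaussian work.

**Divergence filtering.** The source criterion for discarding off-path runs
is visual; the implementation uses two quantitative, configurable rules with
a per-run decision log: (a) completion — final projected displacement below
90% of the largest scheduled distance; (b) work outlier — work at the last
common coordinate deviating from the ensemble median by more than 5×MAD
(with an absolute floor so identical runs are never flagged). A manual
exclusion list is honored first. On the 1-D Langevin fixture, where no run
genuinely diverges, rule (b) occasionally trims a work-distribution tail and
slightly biases the estimate; correctness checks therefore run on the full
prescribed 70-run ensemble, with filtering exercised on constructed
outliers.

**Errors.** Block averaging partitions runs into 5 groups, computes the
cumulant PMF per group and reports the SE of the group estimates; bootstrap
resamples runs with replacement (default 1000 draws, seeded) and reports the
per-bin SD. Identical runs give exactly zero error under both.

## Synthetic fixtures

`gnm_ensemble` builds an anisotropic elastic network (pairwise springs
−(k/d²)(d⊗d) within a contact cutoff) on a helix, near-extended strand, or
compact random-walk backbone, removes the six rigid-body modes by spectral
truncation, and draws i.i.d. frames from N(mean, k_BT·H⁺). It returns both
the samples and the analytic covariance — the oracle for the covariance,
PCA and PRS chains. Random-walk geometries can produce floppy networks (a
low-degree node with near-collinear contacts adds a seventh soft mode); the
generator redraws the walk from its seeded stream until only six soft modes
remain, keeping it deterministic per seed. `pca_balanced_gnm_spec` names the
20-residue helix network (15 Å cutoff) whose first five modes carry ≈50% of
the variance, the regime reported for Cα PCA of RAS trajectories.

`two_state_trajectory` realizes a prescribed mixture over (d1, d2) distance
states in a minimal 4-atom system whose atoms carry the default
Switch I/Switch II atom specs, with the drawn distances realized exactly.

`smd_toy` integrates overdamped Langevin dynamics,
γẋ = −U′(x) + k(x_anchor − x) + √(2γk_BT)ξ, by Euler–Maruyama at a 2 fs
step, recording every 24 fs — the sampling pattern of the reference pulling
protocol — with all runs vectorised over independent noise streams. The
`friction` parameter is the drag coefficient γ in kcal mol⁻¹ ps Å⁻²
(default 10, stable and moderately dissipative at the protocol's pull
speed); a rate in ps⁻¹ would additionally require a particle mass the model
does not otherwise need. The default potential is a tilted quartic double
well (3 kcal/mol untilted barrier, 3 Å minima separation,
−0.5 kcal mol⁻¹ Å⁻¹ tilt) — chosen so a 70-run ensemble resolves the
inter-minimum ΔF well inside run-to-run noise while still crossing a real
barrier; the default pull distance (3.5 Å) spans the wells plus a 0.5 Å
margin, stopping before the steep outer quartic wall where a stiff-spring
completion criterion would misfire. Zero temperature is allowed and yields
deterministic (noise-free) pulling for quasi-static checks. The analytic
potential is returned as ground truth; its exact tilted minima are located
numerically (`well_minima`).

`solvated_toy` places a one-atom solute at the origin with prescribed
numbers of water oxygens at cutoff ∓ 0.1 Å in random directions — planted
ground truth for hydration counting.

## What the fixtures do and do not show

The fixtures reproduce the mathematical structure each estimator assumes —
Gaussian equilibrium fluctuations with known covariance, exact two-state
distance mixtures, near-Gaussian pulling work on a known 1-D landscape,
exact hydration counts. Passing tests therefore demonstrate correctness of
the estimators and conventions, convergence at the stated sampling sizes,
and internal consistency across stages. They do not demonstrate anything
about force-field accuracy, sampling adequacy of μs-scale MD, anharmonic or
multi-basin protein dynamics, or solvent structure; headline numbers from
the real HRAS systems (Table-scale RMSF values, water counts, eigen-RMSF
magnitudes, the ~30 kcal/mol opening barrier) depend on those trajectories
and are recomputable with this package only from the corresponding deposited
data, not from fixtures.

## Problem sizes

Default test and acceptance runs use 20-residue networks (up to 50,000
frames for covariance convergence), 70-run pulling ensembles of ~4,900
samples each, and 1000-direction scans — sizes chosen so the statistical
checks sit well inside their tolerances while the full suite runs in
seconds.

## Known limitations

- The selection language is a conjunction-only mini-grammar (no `or`,
  no parentheses); complex selections are composed in Python.
- GNM frames are i.i.d. samples, so time-correlation-sensitive estimators
  (block SE) see them as uncorrelated; block SE behaviour under real
  autocorrelation is exercised only qualitatively.
- The PMF reader assumes whitespace-delimited logs with a configurable
  column map; exotic engine formats need pre-conversion.
- `pmf_cumulant` drops bins outside the common coordinate support rather
  than estimating from partial ensembles.
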
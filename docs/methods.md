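# Methods

## Model landscapes

The unbinding free-energy profile U(ξ) is a shape-preserving cubic (PCHIP)
interpolant through a small knot set: a repulsive inner wall left of the
bound minimum (U = 0 at ξ = `bound_min`, default 1.0 nm), a smoothstep rise
to `barrier` kJ/mol at `plateau_start` (default 2.3 nm, the separation
beyond which ligand–protein interactions are lost), and an exactly flat
free-state plateau out to the domain edge (default 3.6 nm).  PCHIP keeps
the rise monotone and renders runs of equal knots exactly constant.  An
optional `shoulder=(ξ_s, depth)` inserts a knot `depth` kJ/mol below the
unperturbed flank, giving the intermediate metastable state seen on some
unbinding paths; because the dip is realised through knots, the spline may
overshoot the nominal depth by a few percent immediately beside the
inserted knots.

Typical barrier templates are 64 and 75 kJ/mol (the order of magnitude of
strong lipid–lipocalin binding); these are generator inputs, and all
recovery statements below are relative to the generator's own ground
truth.

## Overdamped sampling

ξ(t) follows the Euler–Maruyama discretisation of overdamped Langevin
dynamics,

    ξ' = ξ − (D/k_BT) ∂(U + w_bias)/∂ξ Δt + √(2 D Δt) η,

with reflecting boundaries at the domain edges.  Defaults: T = 310 K
(k_B = 0.0083145 kJ/mol/K), D = 1 nm²/ns, Δt = 10⁻⁵ ns.  A pre-run
estimate aborts when the expected step exceeds 0.1 nm and warns when Δt is
within an order of magnitude of the stability limit 0.1·k_BT/(D·max|U″|).
The landscape gradient is evaluated from a dense precomputed table (8192
points, linear interpolation) so windows/replicas integrate as one
vectorised batch.  `D = 0` is treated as the zero-noise limit: the noise
is switched off while the mobility keeps the Einstein value of the default
D, yielding deterministic gradient descent.

Umbrella datasets (default 47 windows, centers 1.0–3.3 nm at 0.05 nm
spacing, k = 1000 kJ/mol/nm²) start each window at its center, discard the
first 10% as burn-in, and **decimate the output by a factor 10**: at
Δt = 10⁻⁵ ns the harmonic relaxation time is k_BT/(Dk) ≈ 260 steps, so
adjacent integrator steps are ~99.6% correlated and retaining every step
would buy file size, not information.  With decimation the retained 10⁵
samples per window carry ≈2·10³ effective samples, which keeps the
window-mean force noise (and hence the seed-to-seed spread of the
reconstructed plateau, ≈0.3 kJ/mol) small.  Adjacent-window histogram
overlap is checked post hoc (overlap coefficient of normalised histograms;
a warning names the first gap).

### Pulling runs

Constant-velocity pulls attach a harmonic spring (k = 100 kJ/mol/nm²) to
the coordinate and move its anchor at velocity v.  The instantaneous
spring force carries thermal noise of standard deviation √(k_BT·k) ≈ 27 pN
— larger than the friction-limited signal at slow pulling — so the
**rupture force F_max is defined as the peak of the moving-average force**
with a scale-free window of one tenth of the trace duration; the raw trace
is kept on the returned object.  Pulling runs default to **D = 0.01
nm²/ns** (the umbrella/unbiased default stays 1 nm²/ns): loading-rate
dependence of the rupture force only exists when the frictional relaxation
time k_BT/(Dk) is commensurate with the pulling time per barrier width,
and at D = 1 the whole 0.01–1 nm/ns velocity ladder is quasi-adiabatic
(relaxation 26 ps) and F_max is velocity-insensitive.  At D = 0.01 the
ladder spans the quasi-static-to-driven crossover (relaxation 2.6 ns) and
median rupture forces rise monotonically with velocity, the phenomenology
the force-probe literature describes.  Unit conversion is fixed at
1 kJ/mol/nm = 1.66054 pN.

## WHAM

Histograms use a common grid (bin width 0.01 nm) spanning all samples;
counts are conserved by construction.  The solver iterates the standard
two equations with f_i initialised at 0 (deterministic order), converging
when max|Δf_i| < 10⁻⁶ kJ/mol (cap 10⁵ iterations; the profile is returned
with `converged=False` beyond the cap).  Bins supported by fewer than
`min_counts` = 25 total counts are treated as unsampled (W = +∞, excluded
from the min-0 gauge): a bin with ~25 counts already carries ≈0.2·k_BT of
pure counting noise in W, and such bins otherwise dominate the maximum of
the profile.  Solvability requires the *window overlap graph* (windows
linked when they share a populated bin) to be connected — the correct
condition, under which isolated tail bins are harmless; a break is
reported with the two window centers that fail to overlap.

Bootstrap errors resample complete windows with replacement (windows as
independent data points), re-solve on the original grid (warm-started from
the full-data constants), gauge each replicate to min 0, and report the
per-bin standard deviation across replicates (n = 200 by default;
replicates with a disconnected overlap graph are discarded and counted,
with a warning above 20%).  The bootstrap median itself varies by a factor
~2 between dataset realisations, so Monte-Carlo convergence comparisons
(double the samples, expect smaller errors) should be run paired, i.e.
generated from the same noise stream.

`pmf_summary` detects the free-state plateau as the terminal stretch (≥0.3
nm) where the smoothed |dW/dξ| (moving average over 0.1 nm) stays below 10
kJ/mol/nm; ΔG_unbind is the raw-PMF mean over that stretch (a
noise-averaged estimator of the plateau height), while `barrier` is the
raw maximum, which on a monotone profile exceeds ΔG_unbind by the
upper-order statistic of the per-bin noise (≈0.5–1 kJ/mol under the
default study conditions).

## Force-distribution profiles

Pairwise records store, per frame, the force vector on atom *i* exerted by
atom *j* (kJ/mol/nm); the implied (j,i) record is the exact negation, and
aggregation is invariant under that relabelling and under record order.
Per frame, all vectors between the ligand and a residue's atoms are
vector-summed (so opposing atomic forces cancel, as they physically
should) and the profile is the time average of the summed magnitude in pN;
frames in which a residue has no pair contribute zero.  Key residues are
those strictly above a threshold (70 pN for equilibrium profiles, 40 pN
for pulling, following the conventional mark levels); "markedly increased
under pulling" means above the 40 pN floor *and* above twice the
equilibrium value, with a zero equilibrium value treated as an infinite
ratio.

The fixture generator draws, per frame and residue, a random direction and
a magnitude mean·(1 + 0.2·N(0,1)) clipped at zero, splits the vector over
atom pairs with zero-sum perturbations, and therefore reproduces the
designed means to the law-of-large-numbers accuracy (0.2%/√(n/10⁴)).

## Protonation bookkeeping

A titratable site's effective pKa is its water pKa plus four numeric
perturbation terms (desolvation, hydrogen bonding, electrostatic
reorganisation, Coulombic); the structure-based estimation of those terms
is out of scope and they are consumed as inputs.  Acids are 0/−1
(protonated/deprotonated), bases +1/0.  The reference ligand carries two
phosphate oxygens — treated as independent one-proton sites, matching how
they are enumerated in the titration bookkeeping — and one amino nitrogen;
reference pKas are 4/4/14 carrier-bound and 6/6/11 free in water.  Net
proton exchange is the signed sum of Henderson–Hasselbalch differences
(positive = ligand gains protons on unbinding); the magnitude is the
headline quantity, 0.180 at pH 7 with the reference values, and it is
sensitive at the ±0.02 level to rounding of the free-phosphate pKa near 6.
The isoelectric point solves net charge = 0 by bracketing on pH 0–14 to
|Q| < 10⁻⁶ (error if no acid/base pair or no sign change).  Per-frame pKa
tables yield n(t) against frame 0 and pI(t); frames missing a group are
skipped and logged.

## Pocket geometry

Coordinates are Å throughout; PDB reading/writing goes through biotite
(multi-model files become trajectory frames; alternate locations resolve
to highest occupancy).  vdW radii come from a bundled element table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å; unknown elements 1.70
with a warning).

Superposition is the Kabsch least-squares fit with the determinant
correction that forbids improper rotations (mirror images keep a positive
RMSD); collinear selections are flagged.  Windowed RMSF splits the
trajectory into equal blocks (remainder dropped with a warning), fits all
block frames to the iteratively refined block mean (3 iterations), and
reports the across-block mean and standard error per atom.

The gate is a residue pair (default 102/147, the tyrosine pair separating
the hydrophilic upper from the hydrophobic lower sub-pocket); its metric
is the minimum side-chain heavy-atom distance.  The partition plane passes
through the midpoint of the gate side-chain oxygens, normal to the barrel
axis (first principal axis of the Cα atoms), oriented so a reference point
(default: Cα centroid) lies on the upper side.

Cavity volumes are measured on a cubic grid (default 0.5 Å, probe 1.4 Å):
a grid point is cavity if it lies outside every probe-inflated atom
sphere, is buried (≥18 of the 26 lattice-ray directions hit protein within
12 Å — this is what lets a "closed" sub-pocket be recognised as sealed
rather than leaking into bulk), and is 26-connected to the seed point
(default: the gate midpoint; override it when the gate is closed).  Volume
= point count × grid³; the upper/lower split by the gate plane is exact in
point counts.  Distances and RMSDs are rigid-motion invariant to numerical
precision; grid volumes re-align to the world axes and are invariant only
to a few grid cells (few percent).  Volumes are monotone non-increasing in
the probe radius, and the error against the toy-calyx oracle decreases
with grid refinement.

Hydrogen bonds use donor–acceptor distance ≤ 3.5 Å and D–H⋯A angle ≥ 150°
when hydrogens are present (auto-detected within 1.25 Å of the donor),
falling back to the distance criterion alone for hydrogen-free crystal
structures; occupancy is the percentage of frames with the bond present.

### Toy calyx oracle

The fixture is a closed pseudo-atom barrel: wall, floor and lid carbons
("CA", so the barrel axis falls out of the Cα principal axis) laid out so
the probe-inflated surfaces are tangent to an ideal cylinder of the
requested radius and depth (bead spacing 1 Å, residual scalloping
< 0.05 Å), plus a two-residue oxygen diaphragm ("TYR" 102/147) at 35% of
the depth whose half-discs leave a slit of the requested `gate_gap`
between the two residues (gap 0 seals the lower pocket).  It returns both
the plain cylinder volume πr²·depth and an exact free-volume integral
(closed-form chord areas of the slit cross-section integrated over height)
that also accounts for the diaphragm's intrusion; the two coincide when
the gate is fully recessed into the wall.  An `open_top` variant removes
the lid to exercise the buriedness filter at a real mouth.

## What the synthetic data do and do not emulate

The generators reproduce the *statistical* structure of an unbinding
study: Boltzmann sampling under harmonic biases, window overlap, bootstrap
variability, designed force means with antisymmetric atom-pair records,
and geometrically known cavities.  They do not emulate atomistic couplings
— no orthogonal degrees of freedom or slow conformational gating (window
autocorrelation is purely the 1-D harmonic relaxation), no force-field
energetics, no solvent, and pseudo-atom barrels rather than real side-chain
packing.  Passing tests therefore validate the estimators and geometry
algorithms against ground truth; they do not certify force-field-level
accuracy on real trajectories, and the atomistic headline numbers of
cluster-scale studies (e.g. 60–75 kJ/mol unbinding barriers) enter only as
landscape templates, never as expected outputs.

## Problem sizes

The standard synthetic study used throughout the tests is 47 windows ×
10⁵ retained samples (10⁶ integrator steps) per window, 200 bootstrap
replicates, 5 pulling replicas per velocity, and 10⁴-frame force fixtures
— sizes at which every recovery statement above holds with a comfortable
margin while the whole study remains a minutes-scale computation.
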
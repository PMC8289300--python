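# Methods

This note records the models, conventions and numerical choices behind
`cdx`, in the order of the analysis pipeline.  Units are nm, ps, kJ/mol and
amu throughout; quantities are converted on ingest (PDB Å → nm).

## Slab convention and interface location

The interface normal is +z.  z is treated as non-periodic in every
interface analysis even when the box is formally periodic, because the
vacuum (or frozen-ice) slab breaks translational symmetry along z; x and y
remain periodic and all intermolecular distances use the minimum image on
those axes.  Ice-slab atoms are identified by an explicit frozen-group tag
on the topology, never inferred from coordinates.

The air–water interface is located per frame as the z where the water
number-density profile first falls to 50% of its bulk plateau, scanning
upward; the plateau is the mean density over the central 20–60% of the
occupied z-range, and the half-crossing is interpolated linearly between
bin centres (0.1 nm bins by default), so the estimate is accurate to a
fraction of a bin.  Locating the interface per frame (rather than on the
trajectory average) keeps protein-induced surface deformation from biasing
protein–interface distances.  The ice interface is the maximum z of the
frozen group, which is exact by construction.

## Density and orientation profiles

Molecule positions are heavy-atom centres of mass (robust to hydrogen
placement).  Density profiles are molecule-count histograms along z,
averaged over frames, converted to number density, and normalized by the
mean density over a designated liquid region: the bulk liquid averages to
1 and surface enrichment reads directly as values above 1.  (Other
normalizations — peak = 1, integral = 1 — would change only the scale, not
the shape; bulk-mean normalization was chosen because enrichment factors
are the quantity of interest.)  The default bin width of 0.1 nm resolves
the ~0.4 nm rim separation of the cyclodextrin model without starving bin
counts.

Rim orientation is the cosine between the unit vector from the
primary-rim centroid (C6 atoms) to the secondary-rim centroid (C2/C3
atoms) and +z, binned by cavity-centre z.  cos θ > 0 means the secondary
rim — and with it the open face of the hydrophobic cavity — points toward
the gas phase.  Bins with zero molecules are reported as NaN, not 0.

Proximity counts use the minimum heavy-atom distance between each CD and
the reference group (protein or ice surface) with a 2 nm default cutoff;
the count is strictly `distance < cutoff`, which makes it right-continuous
and non-decreasing in the cutoff.

## Inclusion criterion

A residue is counted as included in a CD cavity when its representative
point — the side-chain heavy-atom centroid, or CA for glycine and
backbone-only models — lies inside a cylinder aligned with the cavity
axis: radial offset < 0.45 nm (slightly less than the 0.5 nm ring radius)
and |axial offset| < 0.40 nm (the rim-to-rim half-height plus margin).
This one-point cylinder test is deliberately simple: it is transparent,
monotone in both thresholds, exactly checkable against a brute-force
geometric oracle, and both thresholds are exposed as parameters.  It is a
documented stand-in, not a claim of equivalence to any particular
published criterion.  Per-residue inclusion frequencies count a residue at
most once per frame regardless of how many cavities contain it.

CD aggregates are connected components of the CD–CD contact graph (any
heavy-atom pair closer than 0.35 nm by default); sizes always partition
the CD set.  The hydration-layer partition coefficient is
K = (n_CD/n_water)_shell / (n_CD/n_water)_bulk averaged over frames, with
the shell defined as everything within 0.6 nm of a protein heavy atom;
K > 1 means CDs preferentially populate the hydration layer.  Without
explicit water the water counts are replaced by seeded Monte-Carlo volume
estimates (10⁴ points).

## Collective variables

- **R_g**: mass-weighted radius of gyration of the protein.
- **dRMSD**: root-mean-square difference of intramolecular pairwise
  distances between a frame and a reference structure.  The pair list is
  built from the *reference only*, keeping pairs with reference distance
  strictly between 0.1 and 3.0 nm; the frame's distances are never
  re-filtered, so the metric is continuous in the frame coordinates.  The
  backbone is N, CA, C, O by default (CA-only is available through the
  atom selection).
- **α-helix content**: every window of six consecutive residues with a
  complete N/CA/C backbone contributes S(RMSD/r₀), where RMSD is the
  optimal-superposition RMSD to an ideal helical template (rise 0.15
  nm/residue, 100°/residue twist) and S(x) = (1−x⁸)/(1−x¹²) with
  r₀ = 0.08 nm.  S is smooth with S(0) = 1, so the CV is continuous and
  bounded by the number of windows (n_res − 5).
- **Interface distance**: |z_COM(protein) − z₀| with z₀ from the
  per-frame interface location.

## Metadynamics reweighting

Well-tempered runs are reweighted with the time-dependent-bias weights
w_t ∝ exp((V(s_t,t) − c(t))/kT), where V is the instantaneous total bias
at the frame (the value a COLVAR file stores — for parallel-bias runs
this is the total applied bias, so no per-CV recombination is needed) and

    c(t) = kT ln [ ∫ds e^{γV/((γ−1)kT)} / ∫ds e^{V/((γ−1)kT)} ]

is evaluated by trapezoid quadrature on a grid at every deposition time,
with log-sum-exp stabilization.  Hills carry already-tempered heights, so
V(s,t) is simply the sum of deposited Gaussians up to t.  c(t) is refused
if the grid is coarser than the narrowest hill.  The first 10% of frames
(the bias-filling transient, whose weights are noisiest) are discarded by
the convenience pipeline `reweight_series`; the fraction is a parameter.
Free-energy surfaces are −kT ln p shifted to min 0, with empty bins NaN.
Multiple walkers are pooled *before* histogramming, each walker's weights
renormalized to mean 1 so walkers contribute in proportion to their frame
counts.  Per-bin FES uncertainties come from a circular block bootstrap
(20 contiguous blocks, 100 replicates by default), which preserves the
serial correlation of the underlying trajectory.

Convergence is monitored as the absolute difference between the CV mean
over the last 10% of the run and the preceding equal-length window,
with a combined block standard error for scale.

## The toy sampler

The reweighting machinery is validated on a 1-D double well
U(s) = k(s²−1)² with k = 8 kJ/mol (a 3.2 kT barrier at kT = 2.494 kJ/mol,
i.e. 300 K) sampled with overdamped Langevin dynamics, dt = 0.01 ps, and
well-tempered deposition at the production parameters: bias factor 15,
initial height 2 kJ/mol, 1 hill/ps.  Two numerical choices matter:

- **Metropolis adjustment (MALA).**  Every Langevin proposal is
  accepted/rejected against the current potential-plus-bias, so the
  invariant distribution between depositions is *exactly*
  exp(−(U+V)/kT), with no time-step discretization bias.  This is what
  makes the zero-height control a clean test: 10⁵ decorrelated samples
  (recorded every 100 steps of a long run) must pass a
  Kolmogorov–Smirnov test against the analytic Boltzmann distribution at
  the 1% level, a test sharp enough to detect the O(dt) stationary bias
  of unadjusted Euler–Maruyama.
- **Friction and hill width.**  friction = 0.5 (diffusion D = 2kT) and
  hill width 0.15 (≈ 0.75 of the thermal well width √(kT/U'') ≈ 0.2) were
  chosen so that a single 10⁵-step run converges: the walker crosses the
  barrier many times once the bias fills the wells.  At this run length
  the reweighted free energy reproduces the analytic surface to ~0.2
  kJ/mol typically at the minima (seed-to-seed spread reaching ~0.5
  kJ/mol in the far tail) and well under 1 kJ/mol at the barrier; the
  residual error is the intrinsic statistical limit of single-run
  reweighting at 10⁵ samples, not discretization.

## Conformational analysis

Pairwise structural comparison uses Kabsch least-squares superposition
(proper rotation enforced; near-collinear selections are rejected because
the rotation is not unique).  Multiple-structure alignment machinery is
unnecessary here because all conformations share one sequence; pairwise
superposition onto a designated reference is a deliberate substitution
for sequence-structure alignment tools.

Daura (GROMOS) clustering repeatedly promotes the frame with the most
neighbours (pairwise superposed RMSD of N–CA–C atoms below 0.1 nm by
default) to centroid and removes it with its neighbours.  Ties in the
neighbour count break toward the lowest frame index, making the result
deterministic; note that with ties the partition can still legitimately
depend on frame order (the tie-break is index-based), which is a property
of the algorithm itself.  Frame weights (e.g. from reweighting) enter
only the reported populations and the "most sampled conformation"
ranking, never the neighbour geometry.

Q_res compares the CA–CA distance patterns of two conformations:
q_i = mean over j with |i−j| ≥ 2 of exp(−(r_ij − r'_ij)²/(2σ²_ij)) with
σ²_ij = |i−j|^0.15.  Because it uses only intramolecular distances it is
invariant under rigid motions of either structure and exactly symmetric
in its arguments.  Self and adjacent pairs are excluded (the standard
convention; the separation threshold is a parameter).  Residues with
q < 0.5 form the unstable patches; patch frequencies across systems are
fractions of systems (optionally stratified by excipient label, with the
stratified frequencies averaging back to the pooled ones), and the
cross-reference report gives a per-residue table, the Spearman rank
correlation between patch and inclusion frequencies, and the Jaccard
overlap between ever-unstable residues and the APR set.

A practical note on scale: σ_ij is of order 1 nm, so Q_res responds to
*large* distance rearrangements.  Sub-nm perturbations leave q ≈ 0.9;
driving q below the 0.5 threshold requires multi-nm displacement of the
affected residues.  The planted-patch recovery fixtures therefore use
strong (5 nm) localized perturbations, and recovery is assessed on the
support of the patch-frequency distribution.

## Synthetic fixtures: what they emulate, and what they do not

The generators plant exactly the statistical structure the analyses are
supposed to recover: z-distributions (uniform, surface-peaked Gaussian,
bulk-only) and tilted orientation distributions p(cos θ) ∝ exp(λ cos θ)
for CDs redrawn i.i.d. per frame; RMSD-controlled perturbations (centred
isotropic Gaussian displacements rescaled exactly to target); frozen ice
grids; and the analytic double well.  The pseudo-CD (ring radius 0.5 nm,
rim offset ±0.2 nm, 7 glucose units with C1/C2/C3/C6 sites) is stylized
rather than chemically accurate — all analysis thresholds are
configurable, so nothing depends on real βCD dimensions.

Consequently, passing tests demonstrate correctness of the estimators and
geometry (oracle equivalence, parameter recovery at known n), not realism
of the physics: frames are uncorrelated in time (no diffusion), water is
a featureless uniform background, there are no capillary waves or
intrinsic-surface effects, no force fields, and the metadynamics
validation is one-dimensional.  Results on real trajectories inherit the
usual MD caveats on top.

## Known limitations

- The air-interface locator needs enough water per frame (≥ ~50 sites and
  a detectable plateau); sparse systems should pool frames first.
- The inclusion criterion is a single-point cylinder test; partial or
  rim-straddling insertions are counted only if the representative point
  enters the cylinder.
- `estimate_ct` assumes hills narrow relative to the grid span and is
  quadrature-based; analytically integrable special cases are not
  exploited.
- Daura clustering is O(n²) in frames (pairwise RMSD matrix); subsample
  long trajectories.
- PDB/GRO round-trips are limited by format precision (10⁻³ nm in GRO;
  10⁻³ Å, i.e. 10⁻⁴ nm, in PDB coordinates).
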
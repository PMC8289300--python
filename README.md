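# cdx

Trajectory analysis for molecular-dynamics studies of cyclodextrin
excipients around proteins at air–water and ice–water interfaces.

Cyclodextrins (CDs) — torus-shaped rings of seven glucose units with a
hydrophobic cavity bounded by a primary rim (C6 atoms) and a secondary rim
(C2/C3 atoms) — are used to protect therapeutic proteins such as G-CSF
against surface-induced denaturation during processing and freeze-drying.
Whether a given CD stabilizes or destabilizes the protein shows up in MD
simulations as a handful of quantitative signatures: where the CD sits in a
slab simulation (surface-enriched vs bulk), how its cavity is oriented at
the interface, whether protein residues enter the cavity, how compact and
structured the protein stays, and which residues carry the conformational
changes.  `cdx` computes all of these signatures from trajectories (or from
its own synthetic fixtures, so the full pipeline is testable without any MD
engine).

## What it computes

- **Interfacial profiles** (`cdx.profiles`): per-frame interface location
  (half-plateau crossing of the water density for air, top of the frozen
  group for ice), normalized number-density profiles along the interface
  normal (bulk mean = 1, so enrichment reads directly as > 1), rim-orientation
  profiles (mean cos θ between the primary→secondary rim axis and +z), and
  proximity counts (CDs within a cutoff, default 2 nm, of the protein or ice
  surface).
- **Inclusion analysis** (`cdx.inclusion`): CD cavity geometry from the rim
  atoms, cylinder-criterion inclusion events per residue, per-residue
  inclusion frequencies, CD aggregate sizes (connected components of the
  contact graph), and a hydration-layer partition coefficient
  K = (n_CD/n_water)_shell / (n_CD/n_water)_bulk.
- **Collective variables** (`cdx.cvmetrics`): radius of gyration R_g,
  α-helix content (smooth switching on the backbone RMSD of six-residue
  windows to an ideal helix), protein–interface distance d, and distance-RMSD

      dRMSD = sqrt( (1/P) Σ_(i,j) [ d(x_i,x_j) − d_ref(x_i,x_j) ]² )

  over the reference backbone pairs with 0.1 nm < d_ref < 3.0 nm.
- **Metadynamics reweighting** (`cdx.reweight`): Tiwary–Parrinello frame
  weights w ∝ exp((V(s,t) − c(t))/kT) with c(t) from grid quadrature,
  weighted CV distributions and free-energy surfaces, multi-walker pooling,
  block-bootstrap error bars, and the last-10% convergence-drift check.
  Reads/writes PLUMED-style COLVAR/HILLS text files.
- **Conformational analysis** (`cdx.confanalysis`): Kabsch superposition,
  Daura (GROMOS) clustering with reweighted populations, the per-residue
  similarity score

      Q_res,i = (1/N_i) Σ_(|i−j|≥2) exp( −(r_ij − r'_ij)² / (2 |i−j|^0.15) )

  on CA–CA distances, unstable-patch extraction (Q_res < 0.5), patch
  frequencies across systems, and cross-referencing against inclusion
  frequencies and aggregation-prone-region (APR) lists like `PHE13-CYS17`.
- **Synthetic fixtures** (`cdx.synthetic`): ideal helices, pseudo-CDs, slab
  trajectories with planted density/orientation structure, RMSD-controlled
  perturbations, and a 1-D double-well U(s) = k(s²−1)² sampled with
  well-tempered metadynamics (Metropolis-adjusted Langevin), whose unbiased
  distribution is known analytically.

## Worked example

```python
import numpy as np
from cdx import synthetic, profiles, reweight
from cdx.reweight import MetaDParams

# slab with surface-enriched CDs whose cavities point toward the vacuum
traj = synthetic.make_slab_trajectory(
    n_frames=50,
    profile_spec=synthetic.ProfileSpec("surface_peaked", peak_z=4.4,
                                       peak_width=0.25, n_molecules=40),
    orientation_spec=synthetic.OrientationSpec("tilted", mean_cos_theta=0.8),
    seed=7,
)
z0 = profiles.locate_interface(traj, kind="air")
prof = profiles.density_profile(traj, "cd", liquid_region=(0.3, 4.7))
ori = profiles.rim_orientation_profile(traj)

p = MetaDParams()  # bias factor 15, 2 kJ/mol initial height, 1 hill/ps
run = synthetic.sample_metad_double_well(p, n_steps=100_000, seed=7)
dist, w, fes = reweight.reweight_series(
    run.times, run.positions, run.bias, run.hills,
    p.bias_factor, p.kT, run.grid, bins=100, range=(-1.8, 1.8),
)
```

prints, with the summary lines shown in the example script:

```
interface at z = 5.00 nm
CD density peak at z = 4.45 nm (7.7x bulk)
mean cos(theta) near the surface = 0.81
reweighted barrier height = 7.9 kJ/mol (analytic 8.0)
```

The interface sits at the top of the 5 nm liquid slab; the density profile
recovers the planted surface peak (4.4 nm) to within one bin and shows
strong surface enrichment; the positive cos θ near the surface means the
secondary rim — hence the hydrophobic cavity — points toward the gas phase;
and reweighting the biased double-well run reproduces the analytic 8 kJ/mol
barrier.

A command-line interface mirrors the library:
`cdx info`, `cdx profile`, `cdx inclusion`, `cdx aggregates`, `cdx cv`,
`cdx reweight`, `cdx cluster`, `cdx qres`, `cdx crossref`,
`cdx simulate-fixtures` (see `cdx --help`).

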
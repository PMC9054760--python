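# mfskit

Conformational-state analysis for MFS-fold membrane transporters.

Major Facilitator Superfamily (MFS) transporters — 12-transmembrane-helix
(TMH) proteins such as the renal organic anion transporter OAT1 — move
substrates by a *rocker-switch* motion: two pseudo-symmetric 6-TMH bundles
rock between an outward-facing (OF, "V"-shaped) and an inward-facing
(IF, "Λ"-shaped) state, with occluded intermediates in between.  `mfskit`
implements the standard computational workflow for characterizing those
states from structures and molecular-dynamics trajectories:

- **Conformational state space.**  Cα coordinates of the 12-TMH core are
  extracted on a fixed arc-length grid, iteratively superposed (Kabsch), and
  decomposed by PCA.  Reference structures labelled OF/OF-occluded/IF/
  IF-occluded span the space; trajectory frames are projected onto it and
  classified by proximity to the pooled family centroids.  PC1 separates
  the V from the Λ arrangement.
- **TMH geometry.**  Helix tilt angles against the bilayer normal
  (F = arccos |a·n̂|), two-segment kink analysis on a dewound Cα trace,
  extracellular/intracellular gating distances between TMH segments, and
  z-dependent pore-radius profiles by a HOLE-style sphere-probe search:
  R(z) = max over probe centers of min over atoms (|p − x_i| − r_vdW,i).
- **Interaction networks.**  Contacts (< 4 Å), hydrogen bonds (donor–
  acceptor ≤ 3.0 Å, D–H···A ≥ 135°), and per-residue-pair time fractions
  defined as summed per-frame bond counts over frames — a salt bridge held
  by two simultaneous H-bonds reports a fraction of 2.0.  The conserved
  intracellular signature motifs (A-motif `G[X3]D[R/K]XGR[R/K]`, `E[X6]R`,
  and the PETL family) are scanned from sequence and the H-bond network is
  partitioned into the intra- and inter-bundle "charge-relay" triads.
- **Free-energy surfaces.**  Gaussian-mixture density estimation on a 2-D
  collective-variable space (by default PC1 × the extracellular TMH1–TMH7
  distance), model size selected by BIC over K = 2..16 with seeded
  restarts, F = −kT ln(ρ/ρ_max) on an 80×80 grid, and steepest-descent
  basins with state populations.
- **Lipid–protein interactions.**  Headgroup-resolved H-bond counts
  (PE ammonium donors vs PC/cholesterol), per-residue lipid occupancy that
  tolerates lipid exchange, >80 % occupancy hotspots, and leaflet density
  maps.
- **Synthetic data.**  Because MD trajectories of this kind are rarely
  shareable, `mfskit.synthetic` generates idealized two-state 12-helix
  bundles, rigid-body gating trajectories with thermal noise, coarse
  PC/PE/cholesterol membrane patches, exact hydrogen-bond fixtures, and a
  motif-annotated stand-in sequence — every analysis is exercisable (and
  tested) end to end without external data.

Structure I/O covers PDB and mmCIF (via gemmi), multi-model PDB, and
DCD/XTC (via mdtraj), with a small atom-selection grammar
(`"resid 212-219 and name CA"`).

## Worked example

```python
import numpy as np
from mfskit import synthetic, confspace, geometry, fes

# OF and IF reference ensembles (20 structures each, 0.3 A thermal noise)
bspec = synthetic.BundleSpec(state_param=0.0, seed=1)   # 0 = OF "V"
of = synthetic.generate_state_ensemble(bspec, 20, 0.3)
if_ = synthetic.generate_state_ensemble(
    synthetic.BundleSpec(state_param=1.0, seed=2), 20, 0.3)
bundle, cmap = synthetic.build_two_state_bundle(bspec)

space = confspace.fit_space_from_structures(
    of + if_, ["OF"] * 20 + ["IF"] * 20, cmap)
print("explained variance (A^2):", np.round(space.explained_variance, 1))

# gating trajectory dwelling at three extracellular opening levels
schedule = np.repeat([0.0, 4.0, 8.0], 100)
traj = synthetic.generate_gating_trajectory(synthetic.GatingTrajectorySpec(
    bundle=bspec, gate_schedule=schedule, noise_sigma=0.5, seed=3))
s1 = geometry.gate_selection(bundle, cmap, tmh=1)
s7 = geometry.gate_selection(bundle, cmap, tmh=7)
gate = geometry.pairwise_com_distance(traj, s1, s7)
proj = confspace.project_frames(traj, cmap, space)
print("gate distance range (A): %.1f to %.1f" % (gate.min(), gate.max()))
print("frame 0 state:", confspace.classify_state(proj.coordinates[0], space))

# free-energy surface and basin populations on (PC1, gate distance)
cv = np.column_stack([proj.coordinates[:, 0], gate])
model = fes.fit_density_model(cv, k_range=range(2, 17), seed=1)
pad = 0.05 * (cv.max(0) - cv.min(0))
ranges = [(cv[:, d].min() - pad[d], cv[:, d].max() + pad[d]) for d in range(2)]
grid = fes.free_energy_surface(model, ranges, (80, 80))
basins = fes.extract_basins(grid)
assign = fes.assign_clusters_and_populations(cv, grid, basins)
print("GMM components:", model.n_components)
print("basins:", basins.n_basins, "populations:",
      {k: round(v, 3) for k, v in sorted(assign.populations.items())})
```

Output:

```
explained variance (A^2): [6841.9   11.8]
gate distance range (A): 47.1 to 56.1
frame 0 state: OF
GMM components: 3
basins: 3 populations: {0: 0.333, 1: 0.333, 2: 0.333}
```

PC1 carries essentially all inter-state variance (6842 Å² against 12 Å²
for PC2), the first frame of the gating trajectory is classified
outward-facing, and the three engineered gate dwell levels (0/4/8 Å of
extra extracellular opening, 100 frames each) are recovered as exactly
three free-energy basins of equal population — the open / intermediate /
closed clustering the method is built to expose.

## Command line

`mfskit --seed 1 --outdir out/ demo-synthetic` generates the synthetic
system and runs every stage, writing CSV/TSV/JSON artifacts and a
`manifest.json` of content hashes (identical config + seed gives identical
hashes).  Individual stages: `build-space`, `project`, `tilt`, `gating`,
`pore`, `hbonds`, `charge-relay`, `lipids`, `fes`, configured through a
YAML file passed with `--config`.

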
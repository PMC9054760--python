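# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `mfskit`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Scope and assumptions

The package analyzes MFS-fold transporters: 12 transmembrane helices in two
pseudo-symmetric bundles (N = TMH1–6, C = TMH7–12), with functional helix
classes A (1,4,7,10; substrate cavity), B (2,5,8,11; inter-bundle
interface) and C (3,6,9,12; lipid-facing).  Systems are assumed membrane-
embedded with the bilayer normal along +z (every geometric routine accepts
an explicit normal).  Coordinates are in Å and assumed imaged/whole;
an optional minimal-image distance is provided for orthorhombic boxes only.
Residue numbering is taken verbatim from input files (no renumbering), so
results can be read against UniProt-numbered residue lists.  Altloc atoms
keep the highest-occupancy conformer (logged); insertion codes are
rejected explicitly rather than silently renumbered.

## The 12-TMH core and cross-structure comparability

Core analyses use Cα atoms of the 12 TMH ranges only.  Because TMH lengths
differ between structures (and between proteins), each TMH trace is
resampled by arc length to a fixed number of points (`points_per_tmh`,
default 20), making core coordinate vectors directly comparable across the
dataset.  A TMH whose length already equals the grid size is passed through
verbatim.  Equal-arc resampling of a refined grid of size 2p−1 nests the
p-point grid exactly, which is the consistency property the tests check.

Helicity is assigned from Cα geometry alone (no hydrogen-bond DSSP — the
synthetic bundles and many deposited models are Cα-reliable): residue
window i..i+3 is helical iff the Cα(i)→Cα(i+3) distance lies in
[4.4, 5.6] Å and the virtual torsion over Cα(i−1..i+2) lies in [35°, 65°]
(a right-handed α-helix sits near 5.05 Å / +50°); all four window residues
are marked, and segments are maximal runs of ≥ 5 residues.  Thresholds are
arguments.

Signature motifs (A-motif `G[X3]D[R/K]XGR[R/K]`, `E[X6]R`, the PETL family
`[P/X]ESXRW[L/X]` / `PET[K/L]`, plus the conserved `LGRR` A-motif tail as
an anchor) ship as data, not code.  The pattern language supports `X`
wildcards, `[Xn]` repeats and `[A/B]` alternatives; matching is
left-to-right non-overlapping by default with an opt-in overlapping mode.

## Superposition and the conformational state space

Rigid superposition is the Kabsch SVD construction with the determinant
correction (proper rotations only); it is validated against an independent
quaternion-eigenvalue oracle to 1e-9 Å in the tests.  The PCA space is
built by iterative mean alignment: superpose all core vectors onto the
current mean, recompute the mean, repeat until the RMS mean shift falls
below 1e-9 Å (a far tighter stop than the 1e-4 Å that would already be
acceptable geometrically; the tight stop makes the data matrix exactly
centered so the rank-(m−1) eigendecomposition conserves total variance to
1e-8, and reference projections reproduce exactly on re-projection).
PC1's sign is anchored so outward-facing references project positive —
principal axes are otherwise sign-arbitrary.

State classification pools occluded variants with their parent family
(OF+OFocc vs IF+IFocc), computes the two family centroids in the first two
PCs, and assigns the nearer one; when the two centroid distances differ by
less than `margin` (default 0.1) times their mean the frame is labelled
intermediate.  The backbone definition for the trajectory-level PCA is Cα
(a flag could widen this; full backbone adds no information for the rigid
synthetic bundles).

## TMH tilt, dewinding, and kink analysis

A helix axis estimated as the leading SVD direction of raw Cα positions is
biased when the trace covers a non-integer number of turns (the winding
leaks into the fit).  `mfskit` removes the winding with a 5-tap symmetric
convolution kernel whose frequency response vanishes exactly at the
canonical 100°/residue α-helix twist; the smoothed points lie on the local
helix axis, and the SVD of those points gives tilt errors below 0.2° on
ideal 20–24-residue helices (raw SVD: up to 0.6°).  Tilt is
arccos |a·n̂| ∈ [0°, 90°], insensitive to the N→C orientation of the helix.

Kinks use a two-segment model on the dewound trace: the split point is the
one minimizing the total residual of a two-line fit; the kink angle is
measured between lines fit to the two segments after excluding a 4-point
margin around the split (the kernel blurs the junction over its own width,
so near-junction points belong to neither line); and the kink residue is
located where the trace switches from preferring one fitted axis line to
the other (interpolated sign crossing of the distance difference).  A
maximum-angle-over-splits rule was rejected: junction-crossing windows
contaminate short-segment axes and systematically overshoot the angle away
from the true junction.  On two ideal 12-residue helices joined at
20–60° the implementation recovers the angle within 1° (3° with 0.15 Å
coordinate noise) and the junction within ±1 residue.  Helices shorter
than max(2·`min_segment`, 12) residues are flagged not evaluable.
Defaults: `min_segment` 6, `angle_threshold` 15°.

## Gating distances and pore profiles

Gating coordinates are Euclidean distances between unweighted Cα centroids
of two selections (for ~8-residue terminal TMH segments the mass-weighted
and unweighted centers are indistinguishable for this purpose).  The helper
`gate_selection` picks the extracellular or intracellular terminal segment
of a TMH by comparing end-segment mean z, so it works for parallel and
antiparallel helices alike.

Pore profiles reimplement the sphere-probe construction: at each z slice
the radius is max over probe centers of min over atoms of
(|p − x_i| − r_vdW,i), clamped at 0.  The search is a 0.2 Å 2-D grid over a
box around the pore axis, restricted to the convex hull of nearby atom xy
projections (this prevents the classic escaping-probe artifact), followed
by coordinate-descent refinement down to 0.005 Å steps; agreement with an
exhaustive 0.02 Å grid is within 0.05 Å.  Slices with no atoms in reach
report the radius cap with a flag.  Van der Waals radii are the Bondi set,
user-overridable.  Snapshots are evenly subsampled (function default 500;
the demo pipeline preset uses 3 snapshots of the synthetic trajectory,
whose pore is static up to noise).  Note that the sphere-probe radius of a
cone is linear in z but offset below the 2-D slice radius, because
neighboring rings bulge into the probe's reach — profiles should be read
as probe-accessible radii, not planar cross-sections.

Dynamic cross-correlation matrices superpose all frames onto frame 0 over
the selection (optional for pre-aligned data), then compute
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with Δr the displacement from
the time-mean position.  Zero-variance atoms produce masked (undefined)
entries rather than propagating NaN.  Rigid-body fitting necessarily
induces O(1/N) spurious correlations on independent noise, so independence
checks are meaningful only for selections of a few hundred atoms; at 200
atoms and 5000 frames the largest off-diagonal |C| on independent noise is
≈ 0.04 (sampling error 1/√n ≈ 0.014).

## Hydrogen bonds, fractions and the charge-relay summary

A hydrogen bond requires donor-heavy···acceptor distance ≤ 3.0 Å and
D–H···A angle ≥ 135° (both configurable; the distance can instead be
measured H···A — conventions differ between analysis packages, and the
choice is explicit).  A 1e-9 tolerance keeps exact-boundary geometries
inclusive.  Donor/acceptor atom definitions for the 20 standard residues
(sidechain + backbone, Amber atom names, HID/HIE/HIP accepted) ship as an
editable table.

Fractions are **summed per-frame bond counts divided by the frame count**,
at residue-pair granularity; a bidentate arginine–glutamate salt bridge
therefore reports 2.0, and values above 1.0 identify multi-H-bond salt
bridges.  An indicator ("any bond this frame") mode is available.  Pairs
below the reporting threshold (default 0.1) are dropped from reports but
kept in the raw table.  Salt bridges are flagged when a basic sidechain
donor group (Arg NE/NH1/NH2, Lys NZ, protonated His) meets an acidic
sidechain acceptor (Asp OD1/OD2, Glu OE1/OE2); backbone-only H-bonds never
qualify.

The charge-relay summary needs the six intracellular signature motifs
(A-motif, E[X6]R, PETL-family, per bundle) and partitions reported pairs
into intra-bundle triad interactions, inter-bundle interactions, and
TMH-contact extensions (one residue outside every motif).  Contact maps
use any-heavy-atom distance < 4 Å at residue-pair level and are verified
against a brute-force all-pairs oracle.

## Free-energy surfaces and basins

Densities are full-covariance Gaussian mixtures fit by EM
(scikit-learn), K scanned over 2..16 with 5 k-means++-seeded restarts per
K and model selection by BIC; fits are deterministic given the seed, and
degenerate covariances are regularized with a 1e-6 ridge.  The surface is
F = −kT ln(ρ/ρ_max) on an 80×80 grid of cell centers (kT = 1 by default;
only relative free energies are meaningful here), with cells below
1e-6·ρ_max masked.  Basins are steepest-descent equivalence classes on the
8-connected grid (memoized descent, verified against exhaustive descent);
minima within one cell are merged.  Samples map to their cell's basin
(out-of-range samples are clipped and counted; masked cells fall back to
the nearest unmasked cell).  For a 0.7/0.3 mixture with equal covariances
the basin depth difference is ln(7/3) kT, which the acceptance script
recovers within 0.05 kT at n = 5000.

The pipeline preset uses (PC1, extracellular TMH1–TMH7 distance) as the
collective variables; the library accepts any 2-D CV pair.  The number of
seeded restarts stands in for the refinement iterations of the original
InfleCS scheme; with BIC selection on these low-dimensional, well-separated
densities the two agree on the basin structure, but barrier heights in
sparsely sampled regions should not be over-interpreted.

## Lipid–protein analysis

Lipid chemistry is reduced to headgroup definitions: PE carries an
ammonium donor (N–HN), cholesterol exactly one hydroxyl donor/acceptor,
PC only acceptors — the hierarchy that makes PE membranes the strongest
H-bond partners and cholesterol the weakest.  Occupancy counts a residue
in contact with a lipid *type* when any heavy atom is within 4 Å of any
headgroup atom of any lipid of that type, so individual lipids may
exchange while the site stays occupied; hotspots are residues above 80 %
occupancy (both thresholds configurable).  The bilayer midplane is the
mean headgroup z, recomputed per frame (robust to drift); leaflet density
maps are normalized 2-D histograms of headgroup positions per type and
leaflet.  Per-type H-bond counts partition the total lipid–protein count
by construction, which is asserted as a property.

## The synthetic-data generators

The generators emulate the statistical structure the analyses assume, not
the physics of a real bilayer simulation:

- **Two-state bundle.**  12 ideal Cα helices (radius 2.3 Å, rise
  1.5 Å/residue, 100°/residue; 24 residues each) evenly spaced on an
  18 Å circle, helix k tilted in its radial plane by
  `tilt_deg`·(1 − 2·`state_param`): +30° flares the extracellular ends
  (OF "V"), −30° the intracellular ends (IF "Λ"), 0.5 is straight
  (occluded-like).  Helix 1 and helix 7 sit diametrically opposite, so
  their terminal segments form the gating pair.  All helices are parallel
  (residue 1 intracellular); real MFS bundles are antiparallel, but every
  downstream analysis is direction-insensitive, so this costs nothing and
  keeps the construction transparent.
- **Gating trajectories** rotate the C-bundle rigidly about an
  intracellular pivot; the rotation angle is solved numerically so the
  TMH1/TMH7 extracellular-segment distance increases by exactly the
  scheduled opening before noise, making the schedule a usable ground
  truth.  Thermal motion is i.i.d. Gaussian coordinate noise (default
  0.3 Å for reference ensembles, 0.5 Å for trajectories — of the order of
  Cα RMSF within a metastable state).
- **Membrane patches** place 2–3 pseudo-atoms per lipid headgroup on two
  leaflets at ±18 Å with uniform xy positions and per-leaflet composition
  by largest-remainder rounding; the membrane trajectory adds a lateral
  random walk (2 Å/frame) wrapped in the box, emulating lipid exchange.
- **H-bond fixtures** are exact donor–H–acceptor triplets at prescribed
  distance and angle; the charge-relay fixture wires four such
  interactions at motif-consistent residue numbers (a bidentate
  Arg162–Glu212 bridge → fraction 2.0, Ser271–Glu270 at 0.7,
  Thr218–Glu506 at 0.05 — below threshold — and the inter-bundle
  Arg219–Glu447 at 1.0).
- **Stand-in sequence.**  A deterministic 563-residue synthetic sequence
  (filler alphabet without E/D/R/K so no spurious matches arise) carrying
  the six signature-motif sequences at their canonical hOAT1 positions
  (153, 212, 269, 390, 447, 505).  It is a scanner control, not a natural
  sequence.  Note the C-bundle A-motif residues (NSLGRR) genuinely do not
  match the canonical `[D/N][R/H]LGRR` pattern — the conserved LGRR tail
  anchors that motif instead, and the canonical pattern incidentally
  matches inside the N-bundle A-motif (DRLGRR at 157), both of which the
  scanner faithfully reports.

All generators are pure functions of (spec, seed).

What passing tests on this data do **not** show: force-field realism,
sidechain chemistry (the bundles are Cα-only; H-bond analyses use explicit
fixtures or full-atom inputs), water, realistic lipid packing or
electrostatics, and the sampling problems of real trajectories
(metastability, slow drift, replica disagreement).  The package
demonstrates that the estimators recover known ground truth under the
noise model; applying them to real MD carries the usual caveats.

## Problem sizes and numerical choices

Test and acceptance problem sizes: 20 + 20 reference structures at 0.3 Å
noise for the state space, 300-frame gating trajectories (three 100-frame
dwells, 0.5 Å noise), n = 5000 for mixture/clustering recovery, 200 atoms
× 5000 frames for the DCCM independence bound, 500-atom fixtures for
brute-force contact equality, single snapshots for pore fixtures.  The
pipeline preset subsamples 3 pore snapshots of the synthetic trajectory;
`pore_radius_profile` itself defaults to 500.  Ties in basin descent
resolve to the first minimal neighbor in scan order; probe refinement
halves its step to 0.005 Å; EM uses a 1e-6 covariance ridge; H-bond
cutoffs are inclusive within 1e-9.

## Known limitations

- The dewinding kernel is tuned to the ideal 100°/residue twist; strongly
  non-canonical helices (3-10, π) retain some winding bias.
- The selection grammar covers residue ranges, atom names, chains and the
  protein flag only — no element, segment or distance-based selections.
- Pore profiling is O(grid × atoms) per slice; for very large systems
  pre-select the pore-lining atoms.
- `classify_state` is a two-family nearest-centroid rule; it does not
  attempt to resolve occluded sub-states.
- The charge-relay summary requires all six motifs; proteins with
  degenerate motifs need manually supplied hits.
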
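# Methods

## Scope and model

`discbelt` treats a nanodisc as a finite discoidal bilayer of DMPC-like
lipids encircled by four scaffold-protein chains arranged as two stacked
rings (a "double belt"): chains A and B in tandem in the upper ring,
C and D in the lower, with the two rings' N→C angular senses either equal
(*parallel*) or opposite (*antiparallel*). The package consumes
coordinates and trajectories (PDB/GRO/XTC/DCD via MDAnalysis, converted
to nm internally); it never propagates dynamics, minimizes energies, or
performs resolution conversion.

Atom order is the identity key across frames; no name matching is done
between frames. Masses are element-based (the 2005 IUPAC standard atomic
weights, under which DMPC's C36H72NO8P sums to 677.93 amu — the per-lipid
figure consistent with the published apoE3-NT/DMPC system-mass range of
298,703–420,730 Da at 4 × 34,000 Da of protein). Coarse-grained inputs are
supported through user-supplied per-bead mass and radius tables.

## Synthetic data: what it emulates, and what it does not

The generator builds idealized nanodisc trajectories whose analysis
targets are known by construction:

- **Lipids.** An explicit-hydrogen DMPC surrogate with the full formula
  (118 atoms) and CHARMM-style names (P; Sn2 tail C22…C214 with H2R/H2S…,
  Sn1 tail C32…C314 with H2X/H2Y…), hex-packed at a default area per
  lipid of 0.60 nm² with phosphate planes 3.4 nm apart — the thickness
  all-atom simulations report for DMPC nanodiscs and pure DMPC bilayers,
  so default fixtures match the real systems the analysis suite is aimed
  at. Head-group geometry is schematic; only the
  phosphorus position, the tail C/H geometry and the masses carry
  information.
- **Tails.** Each lipid's tail direction is tilted from the disc normal
  by θ drawn from a configurable distribution (fixed angle, Gaussian, or
  isotropic). C–H bonds are built perpendicular to the tail axis at
  azimuths that average cos² to exactly ½ (methylene pairs 90° apart,
  terminal methyls 120° apart), so the construction's per-carbon order
  parameter is the closed form S = (3 sin²θ/2 − 1)/2, recorded in the
  ground truth. An optional extra tilt for lipids in the outer rim band
  emulates belt-induced edge disorder.
- **Belt.** Ideal α-helical poly-alanine ribbons (0.15 nm rise/residue)
  wound along the ring at disc radius + 1 nm; rings at ±1.5 nm. The belt
  exercises geometry code, not protein chemistry.
- **Noise.** Per frame, each molecule receives one rigid Gaussian
  translation (default σ = 0.05 nm, 200 frames — the snapshot-averaging
  scale of a production analysis window). Rigid per-molecule noise leaves
  bond directions, and hence the ground-truth S_CD, exact under jitter.
  `perturb_frames` (independent per-atom jitter of a single frame) is the
  separate, deliberately simpler plumbing used for RMSD-statistics tests.

Passing tests on these fixtures shows the *analysis operators* are
correct: they do not show thermodynamic realism (no water, ions,
undulations, protrusions, area fluctuations, or lipid exchange between
leaflets), so quantitative agreement with experiment is out of scope by
design.

## Analysis procedures and numerical choices

**Reorientation.** The bilayer normal is the smallest-variance principal
axis of the phosphate positions (deterministic sign: n_z ≥ 0); frames are
mapped so the lipid center of mass is at the origin, the normal along +z,
and the larger in-plane variance along x (major axis = x — this fixes the
x/y convention in diameter reporting). The covariance criterion assumes
the disc diameter exceeds the bilayer thickness, true of every physical
nanodisc; fixtures below ~60 lipids/leaflet violate it and are not used.

**Density profiles.** 100 uniform bins along one axis; extent defaults to
the system bounding box ± 1 nm. Conversion to kg/m³ uses a fixed slab
cross-section (the orthogonal-plane bounding-box area of the full system
in frame 0), so profile mass integrates back to the selection mass
exactly. Symmetrization pairs bins index-wise about the bin nearest the
requested center — exactly idempotent on the grid, at the cost of the
center snapping by ≤ half a bin. Peak positions are refined with a
3-point parabola. Thickness requires genuine leaflet peaks: maxima below
20 % of the profile maximum are ignored, and the two peaks must be
separated by a valley dropping below half the smaller peak (a monolayer
fails this with "not a bilayer"). Threshold diameters interpolate the
1 kg/m³ crossing linearly between bin centers.

**SASA.** Shrake–Rupley with a deterministic golden-spiral point set
(48 points by default; no RNG), Bondi radii for elements, a single
configurable radius (default 0.264 nm) for coarse-grained beads, and
probe radii 0.14 nm (all-atom water) / 0.265 nm (coarse-grained water).
Only selected atoms occlude. Neighbor search uses a k-d tree; the output
is independent of the search structure. Because the point set is fixed in
the lab frame, SASA is exactly translation-invariant but only
approximately rotation-invariant (≈1 % at 48 points, converging as the
point count grows).

**Superposition and RMSD.** Kabsch via SVD with the determinant
correction, so a proper rotation is always returned; backbone = N, CA, C,
O heavy atoms; each frame is refit onto the reference independently.
Tests cross-check against a quaternion characteristic-polynomial oracle.

**Contacts.** Distances use side-chain heavy atoms only (Gly falls back
to CA). Residue pairs on different chains within the 1 nm prefilter are
tracked per frame; a pair is in contact when its minimum side-chain
distance is below 0.4 nm, and reported at occupancy ≥ 0.5 by default
(configurable; per-frame counts exportable). Polarity classes — polar
{D,E,K,R,H,N,Q,S,T,Y,C,W}, nonpolar {A,V,L,I,P,F,M,G}, mixed =
"nonspecific" — are configurable; the ionic flag marks (R|K|H)×(D|E)
pairs. Configuration comparison takes, per category, the ratio of mean
antiparallel to mean parallel counts over the lipid counts present in
both configurations, rounded to one decimal.

**Order parameters.** Tail carbons are recognised by the C2k/C3k naming
pattern (k ≥ 2; the carbonyl C21/C31 carry no hydrogens); hydrogens are
the H atoms immediately following their carbon in the residue's atom
order, the layout of both the synthetic template and CHARMM-style lipids.
S_CD is averaged over both tails, all selected lipids, all bonds of a
carbon and all frames; |S_CD| is reported per carbon index 2–14. Regions:
*core* = lipid centroid within 3.0 nm (in-plane) of the lipid center of
mass; *rim* = centroid within 1.4 nm of any protein atom (a rim distance
an order of magnitude larger would include every lipid of every disc, so
1.4 nm is the physically meaningful default; it is an explicit
parameter). Region membership is evaluated per frame.

**Escaped lipids.** Single-linkage clustering at 1.0 nm on representative
atoms per lipid (phosphate + the two terminal tail carbons); everything
outside the largest cluster is escaped. Representative atoms rather than
molecule centroids: opposing-leaflet *centroids* of any intact bilayer
sit ≈1.8 nm apart and would always split into two leaflet clusters,
whereas facing tail ends and lateral neighbours link an intact disc into
one component. The 1.0 nm default exceeds the ≈0.83 nm nearest-neighbour
spacing at 0.60 nm²/lipid.

**Builder.** "Unwinding" re-places helical segments end-to-end along a
common axis as rigid bodies (per-segment internal RMSD is identically
zero) with loops rebuilt as extended connectors; an alternative
whole-chain treatment is available by passing no segments. Bending places
each rigid unit on its chord of the target circle; because chord
placement perturbs terminal positions slightly, the ring radius is solved
by bisection so the measured terminal Cα–Cα gap equals the requested
0.5 nm exactly. The lower ring is generated by a proper 180° rotation
about x (antiparallel) or a plain copy (parallel), then shifted to
−3 nm/+3 nm symmetric planes; the two modes share atom count and radius
and differ only in the lower ring's angular sense. Lipid packing reuses
the synthetic hex lattice and refuses to build if any lipid atom would
come within 0.2 nm of the belt. Builds outside the empirically stable
240–420 lipid range warn but proceed.

**Pipeline.** The analysis window is the terminal fraction (default 20 %)
of the trajectory sampled at up to 200 equally spaced snapshots. Stages
run independently; a failing stage (e.g. diameters on a belt-free bilayer
patch) is recorded under `errors` and flags the report partial without
aborting the rest. Reports are plain JSON with units in key names;
identical inputs and configuration give byte-identical reports.

## Problem sizes used in the shipped tests and acceptance script

Synthetic discs of 100–210 lipids/leaflet with 1–10 frames (200 frames
only where a statistic needs them), SASA on envelope selections (P + CA)
for size sweeps, and 10⁵ Monte-Carlo bond orientations for the isotropic
order-parameter fixture. These sizes make every statistic's tolerance
comfortably attainable while keeping a full run in minutes on one core.

## Known limitations

- GRO files carry no chain identifier; chain round-trips are guaranteed
  for PDB only.
- The reference frame for RMSD series is caller-chosen (default: first
  frame of the analysis window); comparisons against NMR-bundle internal
  RMSDs are out of scope.
- Hydrogen reconstruction for united-atom lipids is not implemented; S_CD
  requires explicit hydrogens (united-atom input raises a clear error).
- The builder produces starting structures, not refined geometries: no
  backbone dihedral modelling, minimization, or solvation.
- Density cross-sections use a fixed bounding-box area; absolute density
  values therefore depend on that convention (recorded in the profile),
  while all derived size metrics depend only on peak/threshold positions.
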
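# Methods

This note documents the models, estimators and numerical choices behind
`memtun`, and what the synthetic test systems do and do not establish
about real data.

## Coordinate conventions

All coordinates are ångström; GRO input (nm) is converted on read.  The
bilayer is assumed planar with its normal along z and the protein
(cytosolic) side at +z.  Residue numbering is taken from the input file
as-is: every residue range the analyses use (orientation windows, gate
residues, tunnel entrances, domain ranges) is interpreted in the file's
own numbering, never renumbered.  Masses come from a standard element
table; atoms whose element cannot be resolved are assigned the carbon
mass with a warning, which biases centres of mass only when files lack
element records entirely.

## Orientation descriptors

The orientation of the anchored protein is summarised per frame by

* d — the z-projection of (COM_protein − COM_membrane), mass-weighted,
  signed.  The Euclidean COM distance is available as an option, but the
  z-projection is the default because the membrane defines a preferred
  axis and insertion depth is the quantity of interest.
* α, β — angles between ẑ and two internal reference vectors: v₁ spans
  helix I (midpoints of the Cα atoms of residues 285–289 and 312–316 by
  default), v₂ spans helix C → helix F (127–131 and 197–201).  Both are
  nearly rigid body-internal directions, so α and β reflect whole-body
  orientation rather than internal motion; the `angle_variance_control`
  analysis verifies this by recomputing the angles after backbone
  superposition onto a reference snapshot and histogramming the
  deviations.
* Helix inclination — the angle between ẑ and the dominant principal
  axis (total-least-squares line) of the transmembrane Cα trace, folded
  into [0°, 90°] because a fitted line has no intrinsic sign.
* Heme tilt — the plane–plane dihedral between the heme (normal =
  (NA→NC) × (NB→ND)) and the membrane (normal = ẑ), folded into
  [0°, 90°].
* Height — the maximum protein heavy-atom z minus the mean
  upper-leaflet head-group z.

### Histogram peaks and representative snapshots

Predominant orientations are read off 1-D histograms of d, α and β.
Default bin widths are 0.5 Å for d and 1° for the angles — well below the
typical spreads (2.5–3 Å, 8–11°).  With bins that much finer than the
spread, the raw argmax bin is dominated by counting noise: adjacent bins
near a flat mode differ by far less than √N counts.  The peak is
therefore located on a Gaussian-smoothed copy of the counts (kernel σ of
4 bins, i.e. 4° / 2 Å, still below the spreads) and reported as the
centre of the winning bin of the stated width.  For a symmetric unimodal
distribution this estimator is unbiased; for skewed distributions the
smoothing pulls the estimate slightly toward the mean, which is the
accepted trade-off.  `smooth_bins=0` restores the raw argmax.

A representative snapshot is the earliest (or, for the superposition
reference, the latest) frame whose three parameters all lie within a
window of the peak values.  The window is multiplicative by default
(±1 % of the peak value, e.g. ±1° at α = 100°); an additive mode is
provided because the fractional reading makes the window width depend on
the parameter's numerical magnitude.

## Synthetic systems: what they emulate

The generator module replaces MD trajectories with constructions whose
ground truth is exact:

* Toy bilayer — two leaflets of 7-atom pseudo-lipids (head P/N4 around
  ±20 Å, glycerol-like middle around ±12.5 Å, tails toward z = 0) on a
  jittered grid with spacing 8 Å, i.e. 64 Å² per lipid, matching the
  area per lipid of a fluid PC bilayer.  The three named parts are what
  the contact analysis needs; there is no water, no acyl-chain
  conformational disorder and no undulation.
* Toy anchored protein — an ideal transmembrane α-helix (residues 1–22,
  principal axis aligned exactly to z), a linker strand (23–37) with
  rotatable backbone, the four orientation windows placed so v₁ ∥ z and
  v₂ ∥ x exactly, three phenylalanine rings at configurable centres, a
  planar four-nitrogen heme proxy, and a hollow spherical shell with an
  opening standing in for the globular domain.  Feature placements that
  collide (< 0.5 Å) are construction errors.
* Rigid-body trajectories — per frame, targets (d, α, β) are perturbed
  with independent Gaussian noise and the protein is posed analytically
  so the measured parameters equal the noisy targets exactly (rotation
  mapping the construction (v₁, v₂) onto a direction pair with the
  prescribed z-angles, a uniform random azimuth, and a translation
  fixing the COM separation).  Two orthogonal unit vectors satisfy
  cos²α + cos²β ≤ 1, so jointly infeasible tail draws are redrawn; with
  the default spreads this affects ≲ 0.1 % of draws and leaves the
  marginals effectively Gaussian.  The membrane stays static; frames
  whose protein dips more than a tolerance below the midplane carry a
  clash flag.  Ground truth is recorded per frame in a sidecar table the
  analysis modules never read.
* Helix-pose trajectories — true tilts drawn N(12°, 6°), folded into
  [0, 90]; the folded-normal mean is 12.10°, and the estimator recovers
  each pose's tilt to machine precision because the canonical helix is
  pre-aligned so its principal axis is exactly z.
* Cavity fixtures — a dense spherical shell (point spacing 1.2 Å) around
  an empty chamber with one or two cylindrical channels whose wall atoms
  sit at axis distance (requested radius + r_vdW), making the true
  bottleneck equal to the request; a blocked variant plugs the channel.

Because orientation, fluctuation amplitudes and channel radii are imposed
by construction, passing tests demonstrate the *estimators* are correct
and well-calibrated — not that real bilayer simulations would show any
particular orientation, contact pattern or tunnel behaviour.

## Contacts and membrane regions

Leaflets are split by lipid-centroid z against the bilayer midplane (mean
lipid z).  The head-group (HG) slab extends ±4 Å about each leaflet's
mean head-atom z; the membrane (M) region lies between the two inner HG
boundaries; everything else is cytosol/solvent (C).  The 4 Å half-width
is a declared default covering the phosphate/choline extent of a PC head
group — no experimental slab width exists to calibrate against — and is
configurable.  A residue's region is decided by its heavy-atom centroid,
so each residue has exactly one region per frame; peptide location
strings collapse consecutive duplicates but keep revisits (M,HG,M →
"M-HG-M").

A contact is any protein-residue heavy atom strictly within 4 Å of any
heavy atom of a lipid part (head/middle/tail by atom-name lists),
counted at most once per (residue, part, frame).  Categories: hydrophobic
(L,I,V), aromatic (F,Y,W), hydrophilic (S,T,N,Q), charged (D,E,R,K),
glycine, proline; H, C, M and A are left uncategorised as their contact
counts are negligible in P450-type systems.  Area per lipid is the naive
box-area / leaflet-count estimator; the protein footprint is deliberately
not subtracted (a Voronoi correction is out of scope).

## Flexibility

Superposition is unweighted least-squares (Kabsch, SVD with reflection
guard).  RMSD series fit each frame on one primary set (default: backbone
of the globular domain) and report every named set without re-fitting, so
loop RMSD is measured in the frame of the superposed domain.  B-factors
are (8π²/3)·⟨|rᵢ − ⟨rᵢ⟩|²⟩ per atom, averaged within residues; heavy
atoms by default, Cα-only via the selection argument.  Frames are assumed
pre-superposed; a `presuperpose_on` option removes global rigid motion
first.

## Tunnels

The clearance field assigns each grid node the radius of the largest
sphere centred there that touches no atom: min over atoms of (distance −
r_vdW), clipped at zero, with Bondi-style radii.  Default spacing 0.6 Å
(0.5 Å in the oracle tests), grid covering the structure's bounding box
plus padding.  A tunnel is a widest-bottleneck path: it maximises the
minimum clearance from the start node to a boundary node.  This max–min
objective is solved exactly by best-first Dijkstra (relaxing
bottleneck(v) = max(bottleneck(v), min(bottleneck(u), clearance(v)))) on
the 26-connected grid; test oracles verify exactness against an
independent threshold + flood-fill search.  The best boundary exits with
mutually distinct exit regions (≥ 8 Å apart, a declared default that
prevents returning ten copies of one channel) are reported, each path
resampled to ≤ 200 equidistant segments with linearly interpolated radii.

Profiles are assigned to named entrances — geometric centres of the Cα
atoms of the defining residues — when exactly one entrance lies strictly
within 5 Å of any path segment; two candidate entrances make the profile
ambiguous and it stays unassigned.  Assignment is trustworthy only while
entrances move less than they are separated; `entrance_stability_check`
flags violations.  A tunnel is open iff its bottleneck radius strictly
exceeds 1.2 Å — slightly below the 1.4 Å water-probe radius because
grid-sampled (like Voronoi-sampled) radii systematically read low.  Open
fractions count unassigned frames as closed.  Opening/closing
co-occurrence is the phi coefficient (Pearson correlation of the binary
open series); pairs involving a constant series are reported NaN.  The
analysis samples frames at a configurable interval (default 150 ps).

The grid start point must be supplied (e.g. the heme-proximal cavity
centre); there is no universal automatic choice for proteins with
multiple internal voids.

## Coarse-grain tools

Bead mapping places one bead at the centroid of its member heavy atoms;
hydrogens never contribute.  The elastic network connects backbone beads
strictly closer than 7 Å (ties excluded) with k = 10.75 kcal mol⁻¹ Å⁻²;
beads of an excluded residue range (the membrane-anchor linker, 23–37 by
default) receive no springs at all, which is what lets the anchored
globular domain reorient.  Linker conformers are generated by uniform
(−180°, 180°] rotations about each linker N–CA and CA–C bond; rotations
move everything downstream in the chain rigidly, so bond lengths and
angles are preserved exactly.  Conformers with any moved heavy atom
closer than 3 Å to the anchor or membrane are rejected and redrawn.

Lipid backmapping is exhaustive template fitting: every library
conformer's precomputed bead centroids are Kabsch-fitted onto the CG
beads and the lowest-RMSD conformer wins.  The library is generated
internally by random dihedral sampling of an idealised 13-heavy-atom
PC-like lipid mapped to four beads (head, glycerol, two tails); the
default size is 200 conformers.  Conversion quality is the RMSD between
the CG beads and the beads re-mapped from the reconstructed molecule,
reported whole-molecule (the acceptance quantity) and per bead; the
working bound is 1.5 Å.  No post-conversion energy minimisation is
applied — the RMSD is assessed directly after the rigid fit, and a
steric-relaxation hook is a deliberate no-op since force-field physics
is outside this package's scope.

## Aromatic gate

Rings are the six aromatic carbons (CG, CD1, CD2, CE1, CE2, CZ); d₁ and
d₂ are ring-centre distances (first↔second, first↔third gate residue) and
the gate is open iff d₂ > 7 Å strictly.  The heme-plane frame takes its
first in-plane axis along NA→NC, the second as the NB→ND component
orthogonal to it, the normal as their cross product.  The covered-area
estimator splits the projected points' x-range into 0.2 Å bins; in each
bin the current min-y and max-y points are discarded, three times over,
and the survivors contribute bin-width × (y_max − y_min); bins with
fewer than two survivors contribute zero.  The estimator is thus immune
to a few gross outliers per bin but underestimates very sparsely sampled
areas; with ≥ thousands of points it converges on the true covered area
(a 4 × 2 Å rectangle at 10⁴ points is recovered within a few percent).

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems:
10⁴-frame orientation trajectories on a ~900-atom system, 5·10³-frame
fluctuation trajectories on ≤ 100 atoms, tunnel grids of ~10⁵ nodes, and
a 200-conformer lipid library — sizes chosen so every statistical
tolerance (5–10 %) is comfortably resolved by the sampling noise at that
n.  Every stochastic component takes an explicit seed, and all
generators are pure functions of their parameters and seed.

## Known limitations

* The synthetic bilayer has no conformational disorder; contact
  statistics on it exercise bookkeeping, not lipid physics.
* Grid-based bottleneck radii are lower bounds that converge from below
  as spacing decreases; profiles are only as smooth as the grid.
* Independent per-frame noise means no autocorrelation; time-series
  statistics (e.g. phi coefficients) on synthetic data assume
  exchangeable frames.
* The naive area-per-lipid estimator ignores the protein footprint and
  is biased high for small boxes with a large inclusion.
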
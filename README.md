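# memtun

Geometry and statistics of membrane-anchored protein trajectories.

Microsomal cytochromes P450 and other single-pass membrane proteins sit on
a lipid bilayer with a buried active site reached through transient
tunnels.  Characterising such a system from simulation trajectories takes
a recurring set of measurements: how the protein is oriented on the
membrane, which residues touch the lipids and how deep they sit, how
flexible each region is, when the active-site tunnels are open, and what
the internal aromatic gate is doing.  `memtun` implements this analysis
suite as an importable Python library for structural bioinformaticians and
simulators, together with the coarse-grain modelling utilities that such
studies use up front (bead mapping, elastic networks, template-library
lipid backmapping) and a synthetic-system generator that produces fully
ground-truthed test inputs in place of expensive MD data.

## What it computes

**Orientation** (`memtun.orientation`).  Per frame: the signed
z-projection *d* of the protein–membrane centre-of-mass separation and the
angles α, β between the membrane normal **ẑ** and two reference vectors

- **v₁** = midpoint(Cα 312–316) − midpoint(Cα 285–289)  (along helix I),
- **v₂** = midpoint(Cα 197–201) − midpoint(Cα 127–131)  (helix C → helix F),

α = arccos(**v₁**·**ẑ**/|**v₁**|), likewise β; plus the transmembrane-helix
inclination (principal axis of the Cα trace, folded to [0°, 90°]), the
heme tilt (heme-plane/membrane-plane dihedral) and the height of the
protein above the head-group plane.  Histogram utilities locate the
predominant orientation and select a representative frame whose
(d, α, β) all lie within a window of the histogram peaks.

**Contacts** (`memtun.contacts`).  Residues are classified into membrane
regions M (lipid-tail slab), HG (head-group slab) and C (cytosol), peptides
get N→C traversal strings such as `M-HG-C`; residue–lipid contacts (any
heavy-atom pair < 4 Å, counted once per residue, lipid part and frame) are
tabulated by residue category × lipid part; area per lipid = box area /
lipids per leaflet.

**Flexibility** (`memtun.flexibility`).  Kabsch superposition, residue-range
RMSD time series after a common domain fit, and B-factors
B = (8π²/3)·⟨|rᵢ − ⟨rᵢ⟩|²⟩ per residue.

**Tunnels** (`memtun.tunnels`).  A clearance field (distance to the nearest
atom surface, vdW radii subtracted) sampled on a grid; tunnels are
widest-bottleneck paths from a buried start point to the surface found by
max–min Dijkstra on the 26-connected grid.  Profiles are assigned to named
entrances (Cα centroids of defining residues, 5 Å rule), classified open
when the bottleneck radius exceeds 1.2 Å strictly, and summarised as open
fractions and opening/closing phi-coefficient matrices.

**Aromatic gate** (`memtun.gate`).  Ring-centre distances d₁, d₂ between
three phenylalanines; the gate is open iff d₂ > 7 Å.  Ring mobility is the
area covered by ring centres projected on the heme plane, estimated with
0.2 Å x-bins after three rounds of min/max-discarding (outlier-robust).

**Coarse-grain tools** (`memtun.cg`).  Bead mapping at heavy-atom
centroids; elastic networks (springs between backbone beads strictly
closer than 7 Å, k = 10.75 kcal mol⁻¹ Å⁻², with a decoupled linker range);
random linker-dihedral conformer generation; lipid backmapping by
exhaustive rigid template fitting with the conversion-RMSD quality
criterion (< 1.5 Å).

**Synthetic systems** (`memtun.synthetic`).  Toy bilayers, an annotated toy
anchored protein, rigid-body trajectories whose per-frame (d, α, β) equal
prescribed targets plus Gaussian noise *exactly*, Gaussian-fluctuation
trajectories, and cavity fixtures with known tunnel bottlenecks.

Structures and multi-model PDB trajectories are read and written through
`memtun.structio` (biotite-backed; GRO input in nm is converted to Å), with
a small selection language (`"resid 285-289 and name CA"`, `"role lipid"`,
`"heavy"`, `"backbone"`, boolean operators).

## Worked example

`examples/orientation_analysis.py` generates a 2 000-frame rigid-body
trajectory around a known membrane orientation and recovers it:

```
histogram peaks: d = 39.75 A, alpha = 100.5 deg, beta = 123.5 deg
representative frame (all parameters within 1% of the peaks): 1502
peak errors vs ground truth: [0.25 0.5  0.5 ] (d/alpha/beta)
```

The generating orientation was d = 39.5 Å, α = 100°, β = 123° with spreads
of 2.5 Å, 9° and 8°; the histogram peaks recover it to within half a bin,
and frame 1502 is a snapshot whose three parameters all lie within 1 % of
the peaks — the selection rule used to pick configurations for follow-up
modelling.  The other scripts in `examples/` demonstrate backmapping,
elastic networks, contacts, flexibility, tunnel detection and the gate,
each printing the quantities it computes and what they mean.

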
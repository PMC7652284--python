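# Methods

This note documents the models, defaults and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Data model

A trajectory is a sequence of `Frame` objects (coordinates in Å, per-atom
names/elements/residue labels, an orthorhombic box) plus one `Topology`
carrying structural annotations: strand assignments, the lateral-gate
residue pair, side-chain membership, POTRA ranges, and hydrogen-bond
donor/acceptor lists. Every atom carries one of eight molecular categories
(water, LPS core, lipid A head/tail, phospholipid head/tail, protein,
ion), assigned purely from (residue name, atom name) through an editable
table; the default table covers common CHARMM outer-membrane residue
names, and acyl-chain atoms (C2x/C3x carbons and their hydrogens) are
split from the head groups by a regular expression. The head/tail atom
partition is an operational choice, configurable per system. Coordinates
are treated as wrapped into the primary box; every distance in the package
uses the minimum-image convention. Strand and loop assignments are
user-supplied (from the config or a generator), not auto-detected —
strand numbering is structure-specific.

## Hydrophobic thickness

*Definition.* Thickness is the vertical distance between user-selected
**hydrophobic boundary atoms** of the two leaflets (default selection:
lipid-tail atoms named `C22` — the first acyl carbon — or the synthetic
marker `CB`). Leaflets are split at the mean z of all boundary atoms;
atoms exactly on the midplane count as outer. This operationalises
"hydrophobic thickness" without claiming a unique atom set; the selection
is a config knob.

*Mapping.* The barrel axis is the membrane normal through the xy centroid
of the barrel backbone per frame (not a fitted principal axis — barrels
sit nearly normal to the membrane; for strongly tilted barrels this
underestimates radial distances, a documented deviation risk). Per polar
bin (default 2 Å radial × 10° angular) and per frame, thickness is the
mean z of outer-leaflet boundary atoms minus that of inner-leaflet ones;
bins lacking either leaflet in a frame contribute nothing that frame, and
never-populated bins are masked, not zero-filled. The radial coordinate is
distance from the axis (not from the barrel surface).

*Per-strand averages.* Each angular bin is attributed to the strand whose
backbone-centroid azimuth is circularly nearest; a strand's value is the
atom-count-weighted mean over its bins within a radial band from the
barrel wall (mean backbone radius) outward 10 Å (configurable). Strands
with no populated bins report NaN, never 0.

*Thinned area.* Per frame, each leaflet's boundary surface z(x, y) is
interpolated onto a Cartesian grid (default 1 Å cells) by periodic
in-plane inverse-distance weighting with a 10 Å cutoff and **power 4**.
Power 2 cannot localise in two dimensions — with weight 1/d², every
distance annulus contributes equal total weight, so the estimate smooths
features of any size regardless of sampling density; power 4 makes the
nearest few markers dominate while still averaging noise. Cells whose
centre lies within 2 Å (xy) of a protein heavy atom are excluded, so the
barrel footprint and lumen never count as "thin membrane". The area
counts cells **strictly below** the threshold (default 20 Å), with a
10⁻⁹ Å guard so a uniform membrane exactly at the threshold reports zero
area despite floating-point noise. Both the per-frame series and its mean
are reported, since a time-averaged field would give a different (smaller)
area under noise.

## Lateral gate

Strand separation is the mean of the two cross distances between backbone
N and O of the gate pair (β1 residue A, β16 residue B). The collective
variable projects the same two displacement vectors onto the gate-opening
direction — a unit vector supplied from a maximally open reference state,
not recomputed per frame — and is signed, so over-closing goes negative.

Hydrogen bonds use the donor-heavy-atom-to-acceptor distance (≤ 3.5 Å)
and the D–H···A angle within 30° of linear, the common convention in
trajectory-analysis tools; both thresholds are configurable. Structures
must carry explicit hydrogens (as simulation outputs do); no hydrogen
reconstruction is attempted.

Register classification per frame: NATIVE if the native pair is below the
sliding threshold (default 8 Å) **and** still shares at least one hydrogen
bond; SHIFTED if the native pair has separated past the threshold while
residue A bonds one of the configured alternative β16 partners; OPEN
otherwise — including the transient case of a sub-threshold but unbonded
seam. The 8 Å / ≥1-bond thresholds reproduce the observed sliding
phenomenology and are exposed in the config rather than hard-coded.

## WHAM

Samples are pooled per window (the replica-exchange structure of the
source data is ignored — standard practice) and histogrammed on 0.1 Å bins
over 2–12 Å by default. The self-consistency equations for the window
free energies f_i are iterated until max|Δf_i| < 10⁻⁸ kcal/mol, with a
hard cap of 10⁶ iterations and an explicit error on non-convergence.
k_B = 0.0019872041 kcal/mol/K; T defaults to 310 K. A force constant of
zero is allowed (flat bias), in which case a single window reduces the
estimator exactly to −k_BT ln(histogram). Populated bins that split into
disconnected segments are an error (the segments' offsets would be
arbitrary); adjacent windows sharing no populated bin trigger a warning.
No autocorrelation correction is applied — with the exact-sampling
generator the samples are independent by construction; for real REUS data
this understates statistical error (limitation).

The convergence rule compares consecutive profiles computed on nested
sampling intervals: the change at the **endpoint** — the last populated
bin of the two profiles' common range (not a fixed 12 Å bin) — must be
strictly below 0.2 kcal/mol per added 5 ns block. Well detection searches
a configurable range (default 3.5–5.5 Å) for an interior local minimum and
measures depth against the lower of the two flanking maxima, treating the
profile ends as maxima; a monotone profile reports no well.

## Interaction census and difference metric

For each residue, atoms within 4 Å (minimum image, atom-to-atom over the
side chain, not centroid) are counted by category and accumulated over
frames. Exclusions: the residue's own atoms (its side chain would
otherwise count itself at distance zero); backbone atoms of residues
within ±2 sequence positions ("nearby" is taken as sequence
neighbourhood, configurable — a spatial definition would need a second
cutoff); ions (the seven census categories omit them). Glycine-like
residues with no side-chain atoms fall back to the α-carbon and are
flagged. Residues with zero total contacts carry a NO_CONTACT flag and
undefined fractions.

The difference metric between two systems is the mean, over pairs of an
input pairwise alignment, of the Euclidean norm of the two residues'
7-fraction vectors. It is symmetric, zero iff aligned fractions are
identical, and bounded by √2. NO_CONTACT pairs are skipped and reported.
The pairwise matrix's diagonal uses the identity self-alignment and is
exactly zero by construction of the metric — the package computes it
rather than asserting it.

## SASA and exposure

SASA is Shrake–Rupley with a deterministic Fibonacci-spiral point set
(default 960 points per atom; quadrature error ~1/√n, and the point count
is the accuracy knob). Radii are Bondi van der Waals values; the probe
defaults to 1.4 Å (water). An atom's accessible fraction is the share of
its expanded-sphere points outside every occluder's expanded sphere.

Water exposure of a residue is side-chain SASA with all non-water,
non-ion atoms occluding, divided by side-chain SASA with only protein
atoms occluding, clamped to [0, 1] per frame; side-chain-only areas follow
the exposure data being emulated, with whole-residue area available by
configuring the side-chain sets. Zero denominators flag the frame BURIED
and drop it from the per-residue decile histogram (so decile counts sum to
the number of *defined* frames). Contact areas use the buried-interface
formula (SASA(A) + SASA(B) − SASA(A∪B))/2 on disjoint groups; the
"periplasmic leaflet" group is all inner-leaflet lipid atoms under the
thickness module's leaflet assignment. "Contact area with water" as
accessible-to-probe area is an operational proxy — no package-independent
definition exists for it.

## Synthetic generators

All generators are deterministic per seed (fresh `default_rng` streams;
umbrella windows derive per-window streams from (seed, window index)).

- **Bilayer**: two leaflets of single-atom boundary markers on a lattice,
  at z = ±t(x, y)/2 plus Gaussian noise (default σ = 0.5 Å), where t is a
  base thickness (default 30 Å) minus an optional Gaussian defect. The
  marker density (default 1/15 Å⁻², ≈3.9 Å spacing) is a sampling
  resolution for the thickness field, chosen to resolve defects of
  σ ≳ 8 Å; it is deliberately denser than real per-acyl-chain packing
  (~1/30 Å⁻²) because the generator makes no claim of realistic lipid
  packing, sterics or energetics. The defect's sub-threshold area has the
  closed form π σ² · 2 ln(depth/(base − τ)).
- **Barrel**: strands of residues on a cylinder (strand k centred at
  azimuth 2πk/n), each residue carrying backbone N (+bonded H), O and an
  outward CB; the gate pair is the mid-height residue of strands 1 and n,
  with that residue's strand-n neighbours as sliding partners.
- **Umbrella windows**: exact inverse-CDF sampling of
  exp(−[U + ½k(x−c)²]/k_BT) on a ≤0.005 Å grid — no Markov chain, so
  tests need no burn-in or autocorrelation reasoning. The standard test
  potential is a quartic double well (barrier 2.5 kcal/mol at 7 Å, wells
  at 4 and 10 Å) whose end-of-range slopes (~10 kcal/mol/Å) are holdable
  by the default uniform 20 kcal/mol/Å² force constant on the default
  18-window layout; realistic REUS studies vary k per window, which the
  API supports.
- **Contact environments**: probe residues on a 40 Å grid, each
  surrounded per frame by a fixed number of neighbour atoms on 2.2–3.8 Å
  shells with categories drawn multinomially from target fractions, so
  recovered fractions carry textbook multinomial standard errors.
- **H-bond sets**: donor–H–acceptor triples on a 25 Å grid with ≥0.1 Å /
  ≥2° margins from the 3.5 Å / 30° thresholds on both sides, so counting
  is insensitive to floating-point detail.

What passing tests on these fixtures shows: the estimators recover known
geometry, known potentials and known contact statistics at the stated
tolerances. What they do not show: robustness to curvature-coupled
undulations, lipid protrusions, barrel tilt, hydrogen-position noise or
force-field-specific atom naming in real trajectories — those enter only
through the configurable selections and tables described above.

## Problem sizes and numerical defaults

Test and demonstration runs use 60–100 Å boxes, one to a few tens of
frames, 18 umbrella windows × 5000 samples, and 960-point SASA spheres;
each stage completes in seconds on one core, and estimator accuracy at
these sizes is the quantity the tests pin down. WHAM tolerance 10⁻⁸
kcal/mol; IDW power 4 / cutoff 10 Å; strict thresholds carry a 10⁻⁹
floating-point guard; polar bins that would be ambiguous at θ = 2π are
clipped into the last bin. Degenerate inputs (empty frames, monolayers,
zero-size cells, overlapping SASA groups, donors without hydrogens,
unknown residue names or elements) raise explicit errors naming the
offender rather than propagating NaNs.

## Known limitations

- The barrel axis is the box normal through the backbone centroid;
  strongly tilted barrels would need a fitted axis.
- No autocorrelation or block-bootstrap error bars on PMFs.
- The census's ±2 backbone exclusion and the head/tail atom partition are
  operational defaults, not uniquely determined definitions.
- The CSV trajectory dialect carries no per-frame box; the template
  frame's box applies throughout.
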
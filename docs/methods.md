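# Methods

`gcgrflex` reimplements, as one tested pipeline, the computational analyses
used to characterise the open and closed conformational states of a
two-domain class B GPCR (the full-length glucagon receptor, GCGR): the
inter-domain orientation coordinates and state-probability maps, the
amide-proton accessibility prediction compared against HDX-MS, elastic-
network normal-mode analysis of the open/closed transition, and the
disulfide-crosslink mass-spectrometry arithmetic. The pipeline consumes
trajectory snapshots (multi-model PDB); it does not run molecular dynamics.

## Inter-domain orientation coordinates

The receptor is split into an extracellular domain (ECD) and a
seven-transmembrane bundle (7TM) joined by the TM1 stalk, which hinges at
residue M144. A Cartesian frame is anchored there: origin O at the pivot
Calpha, z along the outward membrane normal, and x the unit horizontal
component of the vector from O to the 7TM centre of mass (so the xz plane
contains the 7TM COM). Per frame we report

* theta — polar angle of **OC** (C = ECD centre of mass) from z, in
  [0, 180] deg; the ECD "swing" towards the membrane,
* phi — the unsigned included angle between the xy-projection of **OC**
  and x, in [0, 180] deg; the ECD "rotation" about z,
* d — |COM_ECD − COM_7TM| in Å.

Choices that were genuinely open:

* COMs are mass-weighted by default (a geometric-centroid mode exists);
  with the synthetic equal-mass blobs the two coincide.
* phi is reported unsigned because the state windows (phi 15–40 deg) do not
  disambiguate sign; a signed value can be recovered from the y-component
  if needed.
* The frame is built on the first frame; each later frame's 7TM Calpha set
  is Kabsch-superposed onto frame 0 (via `scipy` `Rotation.align_vectors`)
  before measurement, so the coordinates report internal motion only.
  Superposition is on by default and can be disabled.
* The membrane normal defaults to +z of the input coordinates (bilayer
  builders align it so); it can instead be estimated from lipid
  pseudo-atom z-percentiles.
* When **OC** projects onto the z axis within 1e-9 Å, phi is undefined:
  the sample is flagged, excluded from maps and counted in the log.

## State maps and windows

The (theta, phi) histogram uses 2.5-deg bins on both axes (chosen so the
open window spans four bins per axis) and is normalised by its maximum bin
count, so the most abundant conformation reads 1. The named windows are
closed rectangles with inclusive boundaries: open = theta 15–25 deg,
phi 20–40 deg; closed = theta 40–45 deg, phi 15–25 deg. A representative
snapshot of a window is the in-window sample nearest (Euclidean, degrees)
to the window centroid, ties resolved to the earliest frame.

## Amide-proton accessibility

A backbone amide proton is inaccessible in a snapshot when any of three
criteria holds:

1. **Hydrogen bonded** — its NH donates to another protein N/O with
   donor-acceptor distance ≤ 0.35 nm and acceptor–donor–hydrogen angle
   ≤ 30 deg. This is the distance/angle convention of the common
   trajectory tools; a donor–H⋯acceptor ≥ 150 deg mode is available.
   Acceptors exclude the donor residue's own atoms; covalently adjacent
   acceptors (e.g. the preceding carbonyl oxygen at ~2.25 Å) fail the
   angle criterion on their own, which we verified on the helix fixture.
2. **Buried** — the proton's solvent-accessible surface area (Shrake–
   Rupley, probe 1.4 Å, 960 fixed golden-spiral points per atom, Bondi
   radii) is ≤ 0.01 Å². The point set is deterministic, so identical
   inputs give bit-identical output. The SASA routine is implemented
   in-package and cross-checked in tests against analytic sphere/two-sphere
   formulas and against `mdtraj`'s implementation on a helix.
3. **Lipid-facing** — the proton is exposed but its z coordinate lies
   inside the configured membrane slab. The slab is a geometric interval
   (from config, or the 10th–90th percentile of lipid-atom z); a
   lipid-contact-count rule would be an alternative operationalisation,
   but a slab is deterministic and parameter-free given the bilayer
   bounds. Lipid atoms never occlude SASA — the bilayer acts only through
   this criterion. Lipids present without a slab raise a configuration
   error rather than silently over-predicting accessibility.

Missing amide protons (crystal-derived snapshots) are reconstructed on N
along the outward bisector of the C(prev)–N and CA–N directions at 1.01 Å;
prolines are excluded (flagged n/a). Chain-start residues without a
preceding carbonyl are excluded from classification. Region percentages
are means ± s.d. over snapshots sampled every 100 ps from the trajectory
tail (default last 500 ns, both configurable); at desk scale the synthetic
fixtures are single snapshots and every frame is used. The comparison
with percent-deuterium tables joins on region labels and flags whether the
predicted apo-minus-bound difference shares the sign of the measured
difference; unmatched regions are listed, never dropped.

All-atom versus heavy-atom occlusion for SASA is configurable
(`heavy_atoms_only`); all-atom is the default since the classifier's
substrate is the proton itself.

## Elastic-network normal modes

A Tirion-style network on Calpha nodes with uniform spring constant gamma
and cutoff Rc = 12 Å (configurable 8–15 Å). The Hessian's off-diagonal 3×3
super-block for a contacting pair is −gamma·r̂r̂ᵀ; diagonal blocks are the
negative row sums, making uniform translations exact null vectors. A
connected network has exactly six rigid-body modes; mode 1 is the lowest
non-rigid mode (the degenerate two-node network has five rigid modes and a
single stretching eigenvalue 2·gamma). More than six near-zero eigenvalues
(tolerance 1e-8 of the largest) raises an error — it indicates a floppy
mechanism or disconnection, which the contact-graph check also reports by
component sizes.

Transition overlap: after superposing structure B onto structure A, the
normalised displacement Δr gives per-mode overlaps |v·Δr|/|Δr| and the
cumulative overlap √(Σ overlap²), which is non-decreasing and ≤ 1. The
hinge fixture is a solid beam of jittered nodes rather than a thin-necked
dumbbell: in a central-force network a thin neck acts as a zero-energy pin
joint (a seventh spurious zero mode), whereas a solid beam is rigid and
its lowest internal modes are the two transverse bending motions — the
analogue of the receptor's ECD-over-7TM swing, which the bending
displacement loads with overlap > 0.6 in modes 1–2.

The qualitative receptor finding (open-structure modes 1–2 versus
closed-structure modes 3–4 driving the transition) is exercised only on
this synthetic hinge, because the representative open/closed receptor
coordinates were never deposited.

## Crosslink mass spectrometry

Monoisotopic arithmetic throughout: water 18.010565 Da, proton 1.007276 Da,
isotope spacing 1.003355 Da, disulfide delta −2.01565 Da (loss of two
hydrogens), N-ethylmaleimide +125.047679 Da as a variable modification on
free cysteines (the crosslinked pair stays unmodified). Residue masses come
from `pyteomics`.

* Digestion: combined trypsin (after K/R) + chymotrypsin (after F/Y/W/L),
  no proline restriction, ≤ 3 missed cleavages counted over the union of
  both site sets, product length 4–100. Implemented via
  `pyteomics.parser.icleave`; tests compare against an independent
  exhaustive enumeration oracle. Note that under these rules a peptide
  like KKKK is legal (length 4, exactly 3 internal missed sites).
* Precursor: mass(α) + mass(β) − 2.01565; m/z = (M + z·1.007276)/z.
  Matching allows the observation to be the monoisotopic or any of the
  first four isotope peaks, within 10 ppm of the candidate mass, ranked by
  |ppm| then isotope index.
* Fragments: b_i (residue sum) and y_i (residue sum + water) ladders per
  chain; any fragment whose span contains the linked cysteine retains the
  disulfide and therefore the intact partner chain plus the delta
  (uppercase B/Y series). A b/y pair at complementary indices of a plain
  chain sums to chain mass + 2 protons at 1+, which is tested as a
  conservation property.
* Spectrum filter: greedy nearest-ppm one-to-one assignment of theoretical
  ions to peaks; the identification passes only if each chain shows ≥ 4
  consecutive fragment indices matched within a single ladder. The case
  change from y to Y at the linked cysteine does not break a ladder — the
  indices belong to one cleavage series.
* Statistical scoring (E-values, FDR) is deliberately absent: the package
  implements the deterministic mass and continuity filters only.

## Synthetic data: what it does and does not emulate

The hinge generator moves a rigid equal-mass pseudo-ECD blob along exact
(theta, phi, d) schedules around a fixed pseudo-7TM blob; optional per-atom
jitter is made mean-free per domain so the COMs stay exactly on schedule.
This validates the geometry pipeline by parameter recovery (to ≤1e-6 deg/Å
in memory; ~4e-4 after a PDB round trip, which quantises coordinates to
0.001 Å) but contains no protein internal structure, no force field and no
kinetics. The bundled apo-like schedule (theta rising 20→50 deg in the
first quarter, then fluctuating near 42 deg; phi stable near 20 deg) and
bound-like schedule (theta vibrating near 20 deg; phi wandering 25–35 deg)
echo the reported simulation phenomenology and the state windows, and the
default problem sizes (400–600 frames, 40-atom blobs) keep every stage at
desk scale. Consequences: passing tests demonstrate correctness of the
measurement and classification machinery, not that a real receptor
trajectory would populate these states.

Helix/strand fixtures are built from ideal internal coordinates
(phi/psi = −57/−47 and −139/135; NeRF chain construction) and carry real
backbone geometry, so hydrogen-bond counts (n−4 for an n-helix) and SASA
values are meaningful; residue 1 receives its amide proton from a virtual
preceding carbonyl so that accessibility fixtures have no unclassifiable
residues. Crosslink spectra contain exactly the requested theoretical ions
plus seeded noise kept > 50 ppm from every theoretical ion.

All generators are deterministic given a seed.

## Numerical conventions and edge cases

* Frames with theta ≈ 0 have undefined phi: flagged, excluded from maps.
* A 7TM COM on the z axis makes the frame degenerate: hard error.
* Histogram boundaries: numpy half-open bins except the final edge; state
  windows are evaluated directly on samples (inclusive on all boundaries),
  not on the binned grid.
* Representative-snapshot ties break to the earliest frame.
* The orientation tolerance of 1e-6 deg/Å applies to in-memory round
  trips; file round trips are limited by the PDB format's 0.001 Å.
* Rigid-mode tolerance 1e-8 of the largest eigenvalue; Kabsch fits use
  `scipy.spatial.transform`.

## Known limitations

* The accessibility percentages printed for the real receptor in the
  source study require its 2-μs membrane MD trajectories, which were not
  deposited; this package reproduces the classifier, not those numbers.
* The slab criterion is a geometric approximation of "accessible only to
  the lipid interface"; systems with highly irregular bilayers would need
  the lipid-percentile estimate or a contact-based rule.
* Digestion implements cleavage-site combinatorics only — no
  semi-specific products, no protein N-terminal methionine handling.
* The PDB reader expects consistent multi-model files; binary trajectory
  formats are out of scope.
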
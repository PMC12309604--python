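# Methods

## Contact geometry

Sugar–aromatic contacts are scored per galactose carbon Cn against the
*nearest* aromatic ring (minimum centroid distance over all rings, assigned
independently per carbon). Two features are computed:

* **d** = |Cn − Ctr|, the carbon-to-centroid distance in Å.
* **θ**, the angle at vertex Cn between the direction to its orthogonal
  projection onto the ring plane and the direction to the centroid. This
  reads the conventional θ(Proj–Cn–Ctr) label as a point triple with the
  vertex at Cn: θ = 0° for a carbon on the ring axis, growing as the carbon
  slides off-axis, and exactly 90° in the limiting case of a carbon lying
  in the ring plane (the projection direction degenerates there; the
  in-plane threshold is 1e-9 Å). An alternative reading — the angle between
  the distance vector and the in-plane projection *vector* — would select
  in-plane geometry and cannot express a "θ below cutoff" stacking
  criterion, so it was rejected. Both angles are computed with `atan2`
  rather than `arccos` so the values are well conditioned near 0° and 90°.

A carbon is a CH−π contact when d < 4.6 Å **and** θ < 50°; both cutoffs are
strict, so values exactly at a cutoff fail. A stacking interaction requires
≥ 3 passing contacts between one sugar residue and one aromatic *residue*;
the two tryptophan rings pool into one group for this threshold because
stacking is defined against the side chain's ring system. The face label is
the sorted set of passing carbons ("135", "3456", …), enabling exact
comparison with the canonical galactose stacking faces.

Ring centroids are means of the member-atom positions; normals come from
the SVD of the centered member coordinates (least-squares plane), which is
robust to slightly puckered rings and exact for planar ones. Hydrogens are
never required: all features use carbon (and ring heavy-atom) positions.

For tryptophan the CVs need a single anchor centroid; the anchor is the
candidate ring with the smallest mean distance over the passing contacts
(ties broken by first encountered). CV1 = d(C1)+d(C2) and CV2 =
d(C4)+d(C6) are then computed against that one centroid.

Aromatic residues considered: Trp, Tyr, Phe always; His behind a
default-on flag (`include_his`), since survey-style analyses do not always
enumerate the aromatic set and the documented default keeps the choice
explicit rather than implicit.

## Structure handling

PDB and mmCIF files are parsed with gemmi; all ATOM/HETATM records are
kept, alternate locations collapse to the highest-occupancy conformer
(ties → first in file order), and only the first model of multi-model
files is used. Resolution and R-factor are read from REMARK 2/3 (PDB) or
`_refine` items (mmCIF) and are represented as missing — never 0 — when
absent. Coordinates are Å throughout; author chain IDs and residue numbers
pass through verbatim. A PDB writer exists for fixtures; its fixed-width
format limits round-trip coordinate fidelity to 1e-3 Å.

## Dataset statistics

Quality filters keep structures with resolution ≤ 2.0 Å and R-factor
≤ 0.2; the boundaries are inclusive ("well-resolved at 2 Å" usage), and
records with missing metadata are excluded with a warning. Redundancy is
removed by greedy, order-dependent clustering: a sequence joins the first
cluster whose founding representative aligns at ≥ 95% identity, where
identity = exact matches / alignment columns of a global alignment
(match +1, mismatch 0, linear gap −1; Biopython's `PairwiseAligner`).
This is deterministic and desk-scale fast; it does not reimplement any
archive's own clustering.

Stacking prevalence is the percentage of structures whose scan found at
least one stacked sugar monomer, reported per ligand class
(monosaccharide/oligosaccharide) and pooled. Display percentages round
half-up to integers; all internal statistics keep full precision.
Enrichment of a trait in a subset uses Pearson's χ² on a 2×2 table with
df = 1 and no continuity correction by default (the intended tables are
large); Yates correction sits behind a flag. Because the exact marginal
construction of such a test (structures vs unique proteins;
subset-vs-rest vs subset-vs-whole) is a modelling decision, the test takes
an explicit table, and the pipeline reports both a structure-level and a
cluster-level construction rather than asserting one.

## Free-energy surfaces from HILLS logs

HILLS files are parsed by FIELDS-header name, not column position; exactly
two CV columns with matching `sigma_<cv>` partners are required, and a
varying bias factor is a format error. The accumulated bias is the plain
Gaussian sum V(s) = Σ_k h_k·exp(−Σ_i (s_i−c_ki)²/(2σ_ki²)), evaluated
axis-separably on the grid.

Two height conventions exist in the wild: files storing as-deposited WT
heights (F = −γ/(γ−1)·V) and files whose heights were already rescaled by
(γ−1)/γ (F = −V). The convention is an explicit flag, default
`deposited`. Energies convert to kcal/mol with the exact factor
1 kcal = 4.184 kJ, and every surface is zero-referenced at its minimum.
Replica combination is the arithmetic mean of zero-referenced surfaces,
re-referenced afterwards ("averaged" replicas are not otherwise
specified; Boltzmann weighting was considered and rejected as the default
because it couples the result to an extra temperature choice).

The default analysis grid is 0.05 Å spacing; the sugar-orientation CV
window of interest is [6, 14] Å × [6, 14] Å, configurable. Basins are the
8-connected component (configurable to 4) of cells within 1.5 kcal/mol of
the global minimum that contains the minimum cell, ties broken by lowest
(row, column) index. Translocation profiles are sampled by bilinear
interpolation along a line CV2 = a·CV1 + b at a fixed CV2 step (default
0.05 Å) and reported against CV2, matching the plotting convention for
two-register sliding. Between two basin windows, the transition value is
the maximum F on the profile segment between the argmin positions,
inclusive of the endpoints so it can never fall below either basin value;
forward/reverse barriers are the differences. A widest-path (minimax)
barrier over all 8-connected grid paths — Dijkstra with max-cost
propagation — serves as the 2D sanity check of 1D line barriers. When an
upper-wall position is supplied, cells beyond it are excluded from basin
and path searches, since the bias there is restrained rather than free.
ΔG is a point estimate (min over a bound mask minus mean over an unbound
mask) with no standard-state or volume correction.

One caveat inherited from typical production inputs: hill widths of
σ = 0.01 Å are unusually narrow for CVs spanning several Å and may
reflect a unit ambiguity in the producing engine's input files. The parser
trusts the file; the toy engine chooses widths appropriate to its
potential.

## Toy Langevin/WT-MetaD engine

The validation engine integrates one particle on an analytic 2D potential
with overdamped Euler–Maruyama dynamics,
s′ = s + (F/ζ)·dt + sqrt(2·k_B·T·dt/ζ)·ξ, and deposits a Gaussian hill
every `pace` steps with the well-tempered height
w0·exp(−V(s)/(k_B·ΔT)), ΔT = (γ−1)·T. Upper walls add κ·(s−bound)^p above
the bound (no ½ factor, matching the common biasing-engine convention;
κ defaults to 150 kJ/mol, p = 2). Hills are written in the HILLS dialect
the analysis side reads, closing the loop.

Defaults and calibration (all values are package choices for the toy
landscape, stated here with their rationale):

* **dt = 0.01 ps, ζ = 1 kcal·ps/mol/Ų, T = 300 K.** The per-step
  harmonic contraction k·dt/ζ = 0.02 keeps the integrator-induced variance
  bias ≈ 1%, so a 10⁵-step harmonic run reproduces the Boltzmann variance
  k_B·T/k within sampling error.
* **pace = 250, w0 = 0.5 kcal/mol, σ = 0.15.** A 2×10⁵-step run deposits
  800 hills whose integrated volume comfortably fills a 5 kcal/mol double
  well; the protocol-style pace of 500 with meV-scale hills would not
  converge at desk scale. γ defaults to 20 (protocol value); `MetaDParams`
  keeps pace = 500 as its constructor default so the protocol
  configuration is representable, and the validation runs pass their own
  schedule explicitly.
* **Units.** Dynamics run internally in kcal/mol regardless of the I/O
  unit; `energy_unit` only rescales w0 on input and hill heights on
  output, which makes kJ- and kcal-configured runs bitwise the same
  trajectory and their analyses equal to machine precision.
* **Seeding.** One root seed; replica r uses seed + r; every result
  object records its seed, and identical seeds give byte-identical HILLS.

The quadrature reference exploits that the toy CVs *are* the coordinates:
the marginal Boltzmann integral collapses and F = U − min U exactly, so
the end-to-end check compares the reconstructed surface against the
analytic potential with no sampling error on the reference side. The
validation condition (three replicas, 2×10⁵ steps, double well h = 5
kcal/mol) recovers the barrier within ±0.75 kcal/mol and the minima at
CV1 = ±1 within ±0.1 across seeds, and the sup-norm reconstruction error
over the visited region shrinks as hills accumulate.

## Synthetic data

**Poses.** The galactose template is an idealized ⁴C₁ chair (uniform
1.52 Å ring bonds, ±0.25 Å pucker, equatorial exocyclic C6), not crystal
coordinates — this removes any archive dependency while preserving the
geometric relations the features probe. A pose orients a chosen face
(1,3,5 or 3,4,5,6 carbons) toward a planar idealized ring (regular
hexagon/pentagon for Phe/Tyr/His, fused-ring indole for Trp) at a given
offset, lateral shift, tilt and azimuth. Per-carbon ground truth is
computed by a deliberately independent oracle — Newell polygon normals and
cylindrical coordinates in a rotated frame (d = hypot(ρ, z),
θ = atan2(ρ, |z|)) — rather than by the geometry module it validates.
On the idealized chair the 3,4,5,6 face at a 3.6 Å offset yields exactly
those four contacts; the flatter 1,3,5 face yields its clean three-carbon
label at slightly larger offsets (≈ 4.1 Å), with nearer poses adding the
2,4 carbons, as expected for an untilted chair. A small optimizer
(`make_pose_with_cvs`) builds poses that realize requested (CV1, CV2)
values, used to represent specific orientations such as the alternative
1,3,5-face binding register at CV1 = 8.8 Å, CV2 = 9.5 Å.

**HILLS.** The deterministic generator deposits one hill per node of an
edge-padded lattice with heights proportional to (γ−1)/γ·(max F − F),
normalized by the discrete Gaussian mass, so the reconstructed surface
equals the target up to Gaussian-smoothing error (the padding removes
edge-truncation error; the sign makes heights non-negative, as a real
engine's are, with the arbitrary additive constant removed by
zero-referencing). The sampled mode emulates a WT run on the grid: centers
drawn from the biased Boltzmann weight, heights decaying with accumulated
bias.

**Metadata.** Mock survey tables realize configured class counts exactly
(round-half-up, not sampled), so statistical outputs are exact and
testable: defaults mirror a published β-D-galactoside survey (58
monosaccharide / 436 oligosaccharide structures at 93% / 66% stacking
prevalence, 53 multi-stacking structures, 29% enzymes overall, 66% among
multi-stacking records, 240 unique proteins). Sequences are random
60-mers shared within a protein cluster, so identity clustering recovers
the configured unique-protein count.

## What the synthetic fixtures do and do not show

The generators emulate the *geometric and statistical structure* of the
real analyses — known contact labels, known reconstructions, known
marginals — and therefore validate the machinery: feature math, nearest-
ring assignment, pooling and thresholds, bias summation, unit handling,
basin/barrier extraction, and the statistics. They do not contain protein
context (binding-pocket sterics, hydrogen-bond networks, solvent), so
passing tests does not certify biological conclusions about any particular
complex; scanning real structures remains supported but its counts depend
on the archive snapshot and are not asserted. The toy engine likewise
validates the WT-MetaD estimator on an analytic landscape, not the
convergence of solvated-protein simulations.

## Known limitations

* No protonation, symmetry/assembly expansion, or multi-conformer handling
  beyond highest-occupancy selection.
* No energy model for contacts; stacking is purely geometric.
* Greedy identity clustering is order-dependent by design (deterministic),
  and identity uses alignment-length denominators; other conventions give
  slightly different cluster counts.
* The ΔG estimate has no volume/standard-state correction and depends on
  user-chosen masks.
* Line profiles are parametrized by CV2 and cannot represent horizontal
  (a = 0) lines; use the 2D minimax barrier for those.
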
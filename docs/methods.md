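# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Helix axes and EF-hand opening angles

A helix axis is the first principal component (leading right-singular
vector) of the centred Cα coordinates of the annotated helix, with the sign
chosen so the axis points from the first to the last residue (N→C). At
least 4 Cα atoms are required; the RMS perpendicular distance of the points
from the fitted line is reported as `fit_rms`. On regular α-helices this
axis agrees with molecular-graphics axis fits (e.g. PyMOL's) to within
~1–2°, which is why angle comparisons across methods carry a ±3° tolerance
in the acceptance suite, while recovery of generator-built helices is
tested at 0.5°.

Inter-helix angles are `arccos` of the dot product of the two *directed*
axes, in [0°, 180°]. Keeping the N→C orientation gives EF-hand opening a
consistent sign: Δθ = θ(holo) − θ(apo), positive for opening. The flip
identity θ(a, b) + θ(a, −b) = 180° is a tested property.

EF-hand topology follows the canonical PEF helix pairing (EF1 = A–B,
EF2 = C–D, EF3 = D–E, EF4 = F–G, EF5 = G–H); the D-helix is shared by EF2
and EF3 and the G-helix by EF4 and EF5, so the hD–hG angle tracks the
movement of the EF1–EF3 sub-domain against the EF4–EF5 dimerization
sub-domain.

Helix boundaries come from one of three sources:

* `auto` — a Cα-geometry assigner: residue windows are helical when
  d(Cα_i, Cα_{i+3}) ∈ [4.2, 5.9] Å, d(Cα_i, Cα_{i+4}) ∈ [4.9, 7.0] Å and
  the four-Cα pseudo-dihedral ∈ [20°, 80°] (ideal α-helix: ≈5.1 Å, ≈6.2 Å,
  ≈+50°); segments ≥ 5 residues are kept, and when 8 helices are expected
  the 8 longest are labelled A–H in sequence order.
* `registry` — shipped residue-range tables for Sorcin, PDCD6 and
  calpain-dVI. These ranges are approximate, literature-informed data, not
  measured constants; they are editable and echoed into every report for
  provenance.
* `file` — a user TSV (`helix_name  chain  start  end`).

For apo/holo Δθ tables the *same* residue ranges are used for both forms,
so a Δθ never conflates boundary re-assignment with conformational change.
A robustness property is tested: shifting ideal-helix boundaries by ±2
residues moves θ by well under 5°.

## Superposition, RMSD and hydrogen bonds

Rigid superposition is the Kabsch least-squares fit (via
`scipy.spatial.transform.Rotation.align_vectors` on centred point sets),
returning a proper rotation, translation and post-fit RMSD; a brute-force
rotation-grid oracle checks optimality in tests. Region RMSD superposes on
an alignment selection (residues paired by author number, Cα only, no
insertion codes) and evaluates other regions *without re-fitting* — the
standard way to show that one sub-domain moves while another stays put.

Hydrogen bonds use a heavy-atom distance criterion only: N/O donor to N/O
acceptor of a different residue, distance ≤ 3.5 Å (default), sorted by
distance. No angular term is applied because the X-ray models this package
targets (1.6–2.1 Å resolution) carry no hydrogens; both directions of an
N–O contact are reported since donor/acceptor roles cannot be assigned
without them. Waters are excluded.

## Metal coordination geometry

Sites are built per hetero metal atom of the requested element; ligands are
all O/N atoms within the cutoff. The 2.9 Å default for calcium covers the
canonical 2.3–2.6 Å Ca–O range plus the longer contacts of bidentate
carboxylates, each oxygen of which counts as a separate ligand (this is how
a hepta-coordinate EF-hand site reaches 7).

Classification is template-based and exact: for n = 7 every one of the
C(7,2) = 21 candidate axial pairs is scored against the pentagonal
bipyramid (axial–axial vs 180°, axial–equatorial vs 90°, azimuth-adjacent
equatorial pairs vs 72°), for n = 6 every one of the 15 perfect matchings
into trans pairs is scored against the octahedron (180°/90°). The deviation
is the mean absolute angular residual of the best assignment; a class is
assigned below 20°, a threshold loose enough for real EF-hand distortion
(jittered ideal sites at σ = 5° score ~5–10°) and tight enough to reject
the wrong template (an ideal pentagonal bipyramid with one equatorial
ligand removed scores ~13° against the octahedron). Classification is
invariant under ligand order and rigid motion by construction.

## Solvent-accessible surface area

SASA is Shrake–Rupley: each heavy atom carries a Fibonacci-spiral mesh
(default 960 points) on its probe-expanded sphere (probe 1.4 Å), and the
accessible fraction is the fraction of mesh points outside every
neighbouring expanded sphere. Radii are single-atom van der Waals values
(C 1.70, N 1.55, O 1.52, S 1.80 Å, default 1.70); waters and hetero groups
(ions, ligands) are excluded from surface and occluders by default,
following protein-surface-program convention. Tests pin the implementation
to the analytic sphere and two-sphere cap formulas and to an independent
Shrake–Rupley implementation (biotite) run with the identical radii array,
so only the sampling/occlusion machinery is compared.

The apo→holo exposure change is
`100 · (SASA_holo − SASA_apo) / max(SASA_apo, 1 Å²)`. The percentage is
taken relative to the apo value because the biological reading is an
*increase* in exposure on calcium binding; the 1 Å² floor keeps fully
buried residues finite and a 5 Å² absolute-increase guard keeps
near-buried residues with tiny denominators from flooding the flagged
list. Which denominator convention the original percentage threshold used
is not documented anywhere authoritative, so both the threshold (30%) and
the convention are exposed as parameters, and set comparisons downstream
use overlap (Jaccard), not exact equality.

Hydrophobic patches are single-linkage clusters of exposed hydrophobic
residues (A, V, L, I, M, F, W, Y, P; exposed = residue SASA ≥ 20% of its
Gly-X-Gly theoretical maximum), linking side-chain centroids within 6.5 Å;
singletons are dropped and patches are ranked by summed exposed area. This
is deliberately a *Hotpatch-like* simplification: the original server's
statistical significance model is unpublished and is not reproduced.

Interface burial computes SASA for the complex and for each partner in
isolation; a residue is buried when isolated-minus-complex SASA ≥ 1 Å².
The identity `SASA_a + SASA_b − SASA_complex = total buried area` is a
tested invariant. No interface thermodynamics (ΔG, significance scores)
are attempted.

## Motif analysis

Patterns are ordered allowed-residue sets. The shipped patterns are the
phage-display consensus `[WYFGM]-[WYFGM]-x-P` and `[DE]-[WYF]` (acidic-Φ);
Φ defaults to the aromatics W/Y/F and is configurable, since the acidic-Φ
class leaves Φ otherwise underdetermined. Scanning reports all overlapping
window matches left to right. Phage-vector linkers (`SSSG-`, `-GGGSGG`)
are stripped on input because they are vector-derived, not selected.
Position-frequency matrices count either equal-length sequences column-wise
or sequences aligned on their first motif hit (anchored mode; hit-less
sequences are dropped and accounted). Condition enrichment is the fraction
of sequences per condition with ≥ 1 hit. No statistical motif discovery
(Gibbs/EM) is included — the patterns are class-defined, not learned.

## SPR kinetics

The model is the plain 1:1 Langmuir surface interaction (association
R(t) = Req·(1 − e^{−(kon·C+koff)t}) with Req = Rmax·C/(C+Kd); dissociation
R(t) = R_end·e^{−koff·t}); mass-transport limitation, drift and
heterogeneous-ligand effects are ignored, matching the single-Kd reporting
the model is meant to reproduce. Curves are baseline-subtracted using the
pre-injection mean when pre-injection points exist. The global fit runs in
log-parameter space (positivity by construction) over all curves at once,
seeded from a fixed multistart grid (kon ∈ 10³…10⁷ M⁻¹s⁻¹ by decade,
koff ∈ 10⁻⁴…10⁻¹ s⁻¹ by decade) with the lowest-cost converged solution
kept. Steady-state analysis fits the binding hyperbola directly and also
reports the Scatchard linearization (Req/C vs Req, slope = −1/Kd), which
matches the nonlinear fit exactly on noise-free data; under additive
response noise the nonlinear fit is the more accurate estimator (a tested
statistical property), which is why it is the primary result.

## Synthetic data: what it emulates, what it does not

The generators produce: ideal α-helix Cα traces (rise 1.5 Å, twist 100°,
radius 2.3 Å — Cα–Cα ≈ 3.8 Å) whose fitted principal axis is aligned
exactly onto the requested direction, so a fixture's axis is known to
machine precision; two-helix apo/holo pairs opened at prescribed angles;
ideal pentagonal-bipyramidal and octahedral Ca²⁺ sites with optional
angular jitter; 16-mer peptide sets with a motif planted at a given
prevalence over a configurable background; and noisy 1:1 sensorgrams. All
are deterministic under their seed, and structures are emitted as standard
PDB so synthetic and real data share one reader.

What they do *not* emulate: side chains and packing (traces are Cα-only
poly-alanine), real secondary-structure irregularity (kinks, 3₁₀ caps),
crystallographic artefacts (alternate conformations beyond the reader's
handling, anisotropy, lattice contacts), electron-density-level ion
identity, or avidity/transport effects in SPR. Passing tests therefore
demonstrate that the *measurement pipeline* is correct and
well-conditioned — axis recovery to 0.01°, template classification exact,
planted quantities returned within their sampling error — not that any
particular real structure has a particular angle. On real coordinate
files the dominant additional uncertainty is helix-boundary choice, which
is why boundaries are data, echoed into reports, and held fixed across
apo/holo pairs.

## Numerical choices and degenerate inputs

* Altloc handling: highest occupancy wins, ties by altloc identifier order
  (single-conformer geometry is what the angle/SASA analyses need).
* Multi-model files default to model 1; a flag selects others.
* Axis fitting needs ≥ 4 points; collinear input is fine (exact line).
  Kabsch needs ≥ 3 non-collinear pairs; collinear sets are an error.
* Report floats are written at fixed 4-decimal precision, giving
  byte-identical re-runs under identical configuration.
* Fibonacci meshes need ≥ 100 points; 960 (default) is within 1% of a
  4000-point computation on fixtures, and within 0.5% of the analytic
  sphere for a lone atom.
* `delta_sasa` requires a shared residue key set; empty selections are
  empty results, not errors, wherever a measurement is merely absent.

## Problem sizes

Test and acceptance computations use desk-scale inputs: 10–170-residue
Cα traces, 7-ligand coordination spheres, 40-residue SASA fixtures,
200-peptide sets and five- or six-curve sensorgram series of ~600 points
each. These sizes put every stochastic check well inside its sampling
tolerance while the full suite runs in a few seconds.

## Known limitations

* Real deposited structures are not bundled; accession-dependent numbers
  are exercised as round trips through synthetic stand-ins built at the
  published values. The readers and CLI accept real PDB/mmCIF files
  unchanged when the user supplies them.
* The auto helix assigner is tuned for clean α-helices; on distorted
  termini it can disagree with DSSP-class assignments by a residue or two,
  which is precisely why registry/file modes exist and Δθ uses fixed
  ranges.
* Patch analysis has no significance model; ranks are area-based only.
* The SPR fitter assumes annotated phases and a single analyte; it will
  fit biphasic data badly rather than refuse it (residual RMS per curve is
  the diagnostic to watch).
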
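# Methods

## Model

A superposition set contains member chains with residue equivalences given by
a sequence alignment: column *j* of the alignment names one residue (or a gap)
in each member. The generative model behind the fit is that each member's Cα
at column *j*, after an unknown rigid motion per member, is drawn from an
isotropic Gaussian with column mean μⱼ and column variance σ²ⱼ. Estimation is
alternating maximisation of the likelihood in (transforms | μ, σ²):

1. initialise every member by an unweighted Kabsch fit onto the seed member;
2. μⱼ ← mean of fitted coordinates over the nⱼ members present at column *j*;
3. σ²ⱼ ← Σᵢ |x̂ᵢⱼ − μⱼ|² / (3nⱼ), floored (below);
4. refit each member to μ by weighted Kabsch, weights 1/σ²ⱼ, using only its
   present columns;
5. stop when the negative log-likelihood (up to constants)
   Σⱼ [3nⱼ log σ²ⱼ + Σᵢ|x̂ᵢⱼ − μⱼ|²/σ²ⱼ] changes by < `tol` (relative), or at
   `max_iter`.

Each step maximises the objective in one block, so the objective trace is
non-increasing by construction; the suite asserts this on every test family.
Missing entries (alignment gaps, unmodelled residues) are excluded from means,
variances and fits; columns present in fewer than two members are dropped and
recorded. Non-convergence returns a flagged result rather than raising, so a
pipeline over many sets degrades gracefully.

This is deliberately a *simplified* maximum-likelihood treatment: one scalar
variance per column (the quantity the downstream outputs consume) rather than
a full hierarchical model with anisotropic covariances and inverse-gamma
priors. The variance floor stands in for the prior's regularisation. The
estimator is therefore not claimed to be bit-compatible with any external ML
superposition program, only to produce the same observables: orientations,
per-column variances, pseudo-B.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `tol` (objective, relative) | 1e-8 | — | well past coordinate precision |
| `max_iter` | 200 | — | families in practice converge in < 20 |
| `variance_floor` | 1e-4 | Ų | keeps zero-noise columns from acquiring infinite weight; ≪ any real coordinate uncertainty |
| `fixed_variance` | off | Ų | pins all σ²ⱼ; turns the fit into iterated unweighted least squares (used for the LS-limit check) |
| gap open / extend | 10 / 0.5 | score | standard affine costs with BLOSUM62 |
| pseudo-B | 8π²σ² | Ų | the crystallographic variance↔B relation |
| motif A anchor radius | 2.5 | Å | the motif A aspartate moves between open and closed active-site conformations |
| motif C anchor radius | 2.0 | Å | motif C is positionally stable |
| monomer trim radius | 22 | Å | selects the superposed polymerase chain plus bound nucleic acid, excludes neighbouring copies |
| ion-site cutoff | 3.0 | Å | beyond it an ion is labeled OTHER |
| DD histogram | 0.1 Å bins over 5.0–9.0 Å | Å | covers the observed 5.3–8.4 Å span of real structures |

Anchor coordinates (common frame): motif A Asp Cα (3.5, −17.0, −11.5), motif
C Asp Cα (10.0, −16.3, −13.8), nascent base-pair centre (14.5, −4.5, −15.5).
Selection boundaries are closed (≤ radius). Distances are computed in double
precision and reported to 2 decimals.

The meA/meB/meB′ ion-site centroids are not published numbers; the defaults
were placed by the implementer in plausible active-site positions consistent
with the anchor geometry (meA between the aspartates and the NTP site, meB
beside the motif A aspartate, meB′ offset outward), pairwise > 4.5 Å apart,
and are user-overridable through `IonSiteModel`. The clustering they formalise
is nearest-centroid with a cutoff — a deliberate, documented substitute for a
by-eye clustering of ion clouds.

## Residue equivalence

The automatic route is a self-contained progressive MSA: k-mer distances
(k = 3, shortened for very short sequences) → UPGMA guide tree
(scipy average-linkage) → profile–profile global alignment with affine gaps
(Gotoh) scoring column pairs by average BLOSUM62 over residue pairs. This is
*not* a state-of-the-art aligner and does not need to be: the ML fit
down-weights columns that are structurally wrong, so occasional misassignments
do not propagate (the corrupted-column test demonstrates exactly this). An
external aligner can be substituted by supplying a curated CLUSTAL file, which
always takes precedence when a set names one. Curated alignments may contain
non-overlapping sections — divergent segments gapped in all other rows — which
parse as ordinary columns and simply contribute no cross-member
correspondences there.

## Orientation inheritance

Anchoring is an unweighted Kabsch fit of the seed's fitted region coordinates
onto the seed's parent-frame coordinates. Unweighted, because the inherited
frame must be matched *exactly* (both coordinate sets are rigid images of the
same atoms, so the optimum is an exact match to rounding), not statistically.
Frames are handed from parent to child **in memory** as transforms; written
PDB files are the 0.001 Å-rounded projection of those frames. Re-deriving a
child frame from a parent's written file would bound seed retention at the
format precision (~5·10⁻⁴ Å RMSD) instead of ~10⁻¹⁴ Å.

Open/closed-style pivot sets need no special machinery: a pivot is a
FULL-region set whose children name a different member (the alternate
conformation) as their seed.

## Synthetic data: what it emulates, what it does not

The generators plant complete ground truth so that every stage is testable:

- **Template.** A compact antiparallel three-helix bundle of ideal α-helical
  Cα segments (rise 1.5 Å, 100°/residue, radius 2.3 Å; consecutive Cα ≈ 3.8 Å).
  A single straight helix was rejected deliberately: it is nearly a rod, so
  rotation about its axis is statistically undetermined and recovery errors
  become intrinsic rather than informative. The bundle provides leverage about
  every rotation axis, like a folded domain.
- **Families.** Member *i* = planted rigid transform of (template +
  per-position Gaussian noise), with optional deletions. The reference
  conditions are 20 members with σ = 0.1 Å on the two outer segments ("core")
  and σ = 1.5 Å on the middle segment ("loops") — the tight-core/divergent-loop
  statistical structure the ML model assumes.
- **Trees.** A chain of sets whose regions grow with depth (13 columns in
  stretches near the ends of all three segments → 40 contiguous columns →
  full traces), each child seeded by a *non-seed* member of its parent to
  exercise pivot-style handoff. The 13 root columns sit near segment ends so
  that the small root fit is well-conditioned; clustering them in one segment
  makes the root orientation ill-determined in a way no real motif selection
  would be. The fixture's root frame is defined as a rigid image of the seed's
  file-precision coordinates (PDB files carry 3 decimals), which is what makes
  exact frame retention measurable.
- **Entries.** Single PDB entries with Asp Cα atoms at the anchor coordinates
  (or at a requested DD along the motif-A direction), optional RNA-like and
  decoy chains, metal HETATMs at ion-site centroids, waters.

Not emulated: side chains, sequence–structure correlation, real indel
statistics, crystallographic artefacts (alternate conformations beyond the
parser tests, NCS copies), and real polymerase fold topology. Passing tests
therefore demonstrate the correctness of the *machinery* — equivalence
mapping, weighting, anchoring, frame bookkeeping, selection geometry — not
that any biological conclusion about real polymerases is reproduced. Running
the bundled tree on real PDB entries is supported but requires the user to
fetch the structures.

### Recovery metric

A multiple superposition recovers planted transforms only up to one global
rigid gauge. The gauge is estimated by precision-weighted Kabsch of the
template onto the recovered mean structure; the per-member error transform is
then gauge⁻¹ ∘ (recovered ∘ planted), whose rotation angle is reported
directly and whose translation is evaluated at the precision-weighted template
centroid — the pivot at which rotation and translation errors decouple.
(Comparing raw translation vectors at an arbitrary origin multiplies the
rotation error by the origin's lever arm and measures nothing useful.)

## Numerical choices

- Kabsch reflection correction via the sign of det(V Uᵀ); degenerate inputs
  (< 3 positively weighted points, or second singular value < 1e-10 of the
  first, i.e. collinear/coincident sets) raise `DegenerateFitError`.
- Altloc resolution: highest occupancy wins, ties broken by altloc character
  order — deterministic single-conformer traces.
- Multi-model files: first model only (crystal-structure inputs).
- Residue order is file order, not numeric sort (non-monotonic numbering and
  insertion codes survive); insertion codes are part of residue identity.
- Zero-occupancy atoms and deuterium are treated as ordinary atoms.
- No check for strict-NCS duplicates; duplicate inputs produce duplicate
  outputs, including in ion pooling (no deduplication).
- Determinism: the pipeline contains no randomness; generators are pure
  functions of (spec, seed). Rerunning any command on identical inputs
  produces byte-identical outputs (the run manifest's timestamp is the sole
  exception, and it lives outside the scientific outputs).

## Problem sizes

Tests and the acceptance script use 60-residue templates, families of up to
20 members (200 for the noise-calibration check), two-level trees with 3
members per set, and a 10⁵-rotation brute-force oracle on 25 15-point clouds —
sizes chosen so the full suite completes in well under a minute while every
statistical assertion retains comfortable margin. The tree machinery itself
is size-agnostic; the bundled configuration describes the full 12-set
polymerase tree and runs unchanged on user-fetched PDB entries.

## Known limitations

- Isotropic per-column variances; no anisotropic tensors or model selection.
- The built-in MSA is adequate for close homologues and curated-alignment
  workflows, not for remote-homology alignment; curated files are the intended
  route for divergent sets (as they were for the picornaviral sets).
- mmCIF is not read; assemblies/symmetry are not expanded (reoriented files
  deliberately omit symmetry records, which would be invalid anyway).
- Fitting uses Cα atoms only.
- The bundled tree's member lists beyond the documented entries are
  curator-editable placeholders, and the curated picornaviral alignment file
  is not shipped.
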
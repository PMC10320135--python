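# Methods

This note documents the model behind `oligoqa`, the parameter choices that
matter, the numerical conventions, what the synthetic fixtures do and do not
emulate, and the design decisions taken where the design was genuinely open.

## The consensus model

The jury estimates the quality of each model in an ensemble as its mean
pairwise similarity to every other model of the same target. The underlying
assumption is the usual one for consensus quality estimation: predictors make
partially independent errors, so the region of conformation space where many
models agree is more likely to be near the truth than any single outlier.
This assumption fails for ensembles with systematically correlated errors
(e.g. twenty models from one predictor stuck in the same wrong assembly
mode); in that regime the jury confidently rewards the consensus error, which
is a known and accepted property of consensus methods, not a defect of this
implementation. Single-model mode substitutes an explicit reference set for
the co-model ensemble and inherits that set's biases instead.

Pairwise matrices are deliberately **not symmetrized**: entry (i, j) scores
model *i* with model *j* acting as reference, and model *i*'s jury score uses
row *i* only. oligo-lDDT and DockQ are direction-sensitive (their pair/contact
universe is defined on the reference side), so (i, j) and (j, i) legitimately
differ.

## Metrics and their parameters

All defaults are module-level constants so alternative parameterizations can
be passed or patched explicitly.

| parameter | value | role |
|---|---|---|
| lDDT inclusion radius R₀ | 15 Å | which reference atom pairs are scored |
| lDDT thresholds | 0.5, 1, 2, 4 Å | distance-difference tolerances |
| QS contact scheme | CB (CA for Gly), 12 Å | inter-chain contact definition |
| QS weight kernel | w(Δ) = max(0, 1 − Δ/12) | distance-agreement weight |
| Fnat contacts | any heavy atom, 5 Å | native-contact definition |
| interface residues | any heavy atom, 10 Å | iRMS set and local flags |
| DockQ scales | 1.5 Å (iRMS), 8.5 Å (LRMS) | RMSD-to-score transforms |
| GDT thresholds | 1, 2, 4, 8 Å | per-threshold CA fractions |

Conventions fixed where references leave latitude:

- **QS weight kernel.** QS-score implementations differ in the weighting of
  shared contacts; the linear kernel above is this package's declared
  convention, isolated in `complex_metrics.qs_weight` so another kernel can
  be swapped in without touching anything else. The "official-style" lDDT
  jury component is the same internal lDDT at the standard parameterization;
  one faithful implementation serves at desk scale rather than shelling out
  to an external binary.
- **lDDT pair universe.** All heavy-atom pairs across different residues
  within R₀ are scored, intra- and inter-chain alike (under the chain
  mapping). This makes the oligo score degrade smoothly for both fold and
  assembly errors and yields a defined score for every residue, which the
  QMODE2 output requires.
- **lDDT comparison is strict** (|Δd| < t), and a residue with no reference
  pairs inside R₀ is excluded from the global mean rather than defaulted.
- **DockQ aggregation** over a multimer is the unweighted mean over all
  reference interfaces (chain pairs with ≥ 1 native contact at 5 Å):
  deterministic and symmetric across interfaces; no size weighting is
  implied by the formula itself.
- **Receptor choice** for LRMS: the side of the interface with more
  residues; ties go to the lexicographically first reference chain id.
  Backbone = {N, CA, C, O}, missing O tolerated.
- **GDT search.** The exact GDT maximum is combinatorial; the implementation
  uses the standard deterministic seed-and-extend heuristic: every
  contiguous window of lengths {3, 5, 7} seeds a superposition that is
  iteratively re-fit on its within-threshold subset (max 10 iterations);
  when fewer than 3 residues fall within threshold the re-fit uses the 3
  closest pairs, which lets the search escape seed windows contaminated by
  displaced residues. The reported value is a deterministic lower bound on
  the exact maximum; on small cases it matches an exhaustive-seed oracle
  (all window lengths, iterated to convergence) to within 1 GDT unit.

## Chain mapping

Quaternary comparison needs a bijection between model and reference chains,
ambiguous whenever identical chains are interchangeable. Chains map only
within exact-sequence groups (point mutants are distinct groups — a
documented limitation, chosen for determinism). The objective is the QS
shared-contact score evaluated under the candidate mapping, computed cheaply
by re-keying precomputed contact maps. Groups of ≤ 6 copies are searched
exhaustively (≤ 720 permutations per group); larger groups use a greedy
assignment by contact-profile similarity followed by one round of
pairwise-swap hill climbing. Ties prefer the first candidate in the
deterministic enumeration order (sorted chain ids).

## Score combination

The component set is {dockq_jury, qs_jury, lddt_jury}. Published variants of
this kind of server combine more component scores with trained weights; the
trained combinations are not public, so this package uses transparent,
parameter-free stand-ins and exposes the weights:

- **linear variant**: weighted arithmetic mean, equal weights by default;
  weights are normalized silently (logged) and recorded in output
  provenance, so trained weights can be dropped in.
- **rank variant**: Borda aggregation — each component contributes its
  within-ensemble ranks (1 = best, ties share the mean rank);
  `rank_score = 1 − (mean_rank − 1)/(n − 1)` maps to [0, 1]. Final ordering
  breaks ties by the linear score, then model name, so reruns are
  byte-identical.
- **single-model variant**: component scores are means over the reference
  set; combination as in the linear variant.

Local scores are the mean per-residue oligo-lDDT over all of a model's
comparisons. Every residue gets a value (QMODE2 needs one); a residue
unscored in every comparison takes the sentinel 0.0, and interface residues
(10 Å, computed on the model itself) are flagged in the result rather than
scored by a separate interface-only metric.

## Synthetic fixtures

The generator builds idealized multimers: each chain a parametric α-helix
(rise 1.5 Å, twist 100°/residue, backbone N/CA/C/O plus CB except glycine),
chains placed on a ring with adjacent axes 9.5 Å apart so neighbouring
chains are guaranteed CB contacts. Sequences are poly-alanine with one
glycine at a group-specific position, making sequence groups distinct and
exercising the glycine CA-for-CB fallback. A 0.05 Å seeded per-atom jitter
is baked into every reference: a perfect n-fold ring is *exactly* symmetric,
which makes all same-sequence chain mappings tie exactly and lets arbitrary
tie-breaks, rather than structure, decide comparisons; real complexes carry
no such exact coincidences, and the jitter makes generated references
generic while keeping them deterministic per seed.

Decoys add seeded i.i.d. Gaussian coordinate noise, optionally a rigid
displacement of one chain, and optionally a relabelling of same-sequence
chains. Labelled ensembles space noise levels evenly across a σ range and
attach true oligo-lDDT/QS/DockQ scores computed against the unperturbed
reference with this package's own metrics.

What the fixtures do **not** emulate: real protein chemistry (side chains,
clashes, secondary-structure diversity), realistic error modes (domain
swaps, register shifts, predictor-correlated errors), or realistic chain
lengths. Tests passing on these fixtures demonstrate the correctness of the
arithmetic, the mapping search, the jury logic and the formats — not that
the jury's accuracy on real predictor ensembles matches its accuracy here.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own fidelity/cost trade-offs: self-identity and
oracle checks run on multimers of 8–20 residues per chain (small enough for
O(N²) brute-force enumeration oracles); noise-monotonicity uses A2 dimers of
12 residues per chain, 20 seeds per σ level; ranking recovery uses 50
ensembles of 20 decoys of an A2 dimer with 40-residue chains. The 40-residue
choice is deliberate: much shorter chains give interfaces with single-digit
native contact counts, where DockQ's Fnat and RMSD terms are dominated by
counting noise in a way no realistic complex is, while 40 residues already
yields well-populated interfaces at a few seconds per ensemble.

## Numerical notes and degenerate inputs

- Superposition uses the Kabsch/least-squares rotation
  (`scipy.spatial.transform.Rotation.align_vectors`, proper rotations only);
  the RMSD is recomputed from the transformed coordinates, which is accurate
  to ~1e-15 where the solver's residual norm is only good to ~1e-8.
  Collinear point sets are rejected (the rotation about the line is free).
- Identical-structure comparisons return exactly 1.0 for lDDT/QS/Fnat and
  exactly 100.0 for GDT_TS; DockQ's RMSD terms at the optimum are 1.0 to
  within double-precision rounding (≤ 1e-12).
- Contact maps store unordered residue pairs once, keyed canonically; the
  heavy scheme keeps the minimum atom distance per pair.
- Chain-mapping and Borda tie-breaks are deterministic (enumeration order /
  linear score / model name); reruns of any mode are byte-identical.
- Undefined scores (no contacts, no shared atoms, empty interfaces) raise
  typed errors rather than returning 0; the jury layer records such pairs
  as missing and excludes them from means, erroring only if a model has no
  defined comparison at all.
- Models lacking residues or atoms present in the reference are scored on
  the shared subset (lDDT universe, backbone selections); residues without
  CA are dropped at parse time, matching backbone-incomplete CASP files.

## Known limitations

- Exact-sequence chain grouping: near-identical chains are never considered
  interchangeable.
- The greedy mapping path (> 6 copies of one chain) is a heuristic; the
  exhaustive guarantee covers ≤ 6 copies, which spans common assemblies.
- mmCIF input is not supported (PDB and the CASP TS dialect only); nucleic
  acids, ligands and waters are excluded from all scoring.
- Jury accuracy claims are established on synthetic ensembles only (see
  above); no benchmark against experimental datasets ships with the
  package.
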
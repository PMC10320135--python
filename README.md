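# oligoqa

Consensus ("jury") quality estimation for models of protein quaternary
structure.

When several alternative 3D models of the same protein complex are available
— e.g. the outputs of assembly predictors for one target — their quality can
be estimated *without the native structure* by comparing every model against
every other model: models that resemble the consensus of the ensemble tend to
be accurate, outliers tend not to be. `oligoqa` implements this jury approach
end to end for multimers, including self-contained implementations of the
underlying complex-comparison metrics, the chain-mapping search they require,
and the CASP-style output formats used to report predicted quality.

## Who this is for

Structural bioinformaticians ranking candidate complex models (e.g. choosing
the top 5 of 20 predictor outputs), and method developers who need
deterministic, desk-scale reference implementations of oligo-lDDT, QS-score,
DockQ and GDT_TS with graded synthetic decoy ensembles to test against.

## The method

**Pairwise metrics.** For a model *M* scored against a reference *R* (another
model, or a native structure) under a chain mapping:

- **oligo-lDDT** — superposition-free: for every heavy-atom pair of *R* in
  different residues within the inclusion radius R₀ = 15 Å, the model
  distance is compared with the reference distance at thresholds
  0.5/1/2/4 Å; a residue's score is the mean preserved fraction of its
  pairs, the global score the mean over residues. Inter-chain pairs are
  included, which makes the score sensitive to assembly errors.
- **QS-score** — from inter-chain CB contacts (CA for glycine) at 12 Å:
  `QS = Σ_shared w(|d_M − d_R|) / (N_shared + N_M-only + N_R-only)` with
  `w(Δ) = max(0, 1 − Δ/12)`.
- **DockQ** — per interface:
  `DockQ = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3`, where Fnat
  is the fraction of native heavy-atom contacts (5 Å) recalled, iRMS the
  backbone RMSD over interface residues (10 Å definition), and LRMS the
  ligand-chain backbone RMSD after receptor superposition. A multimer's
  DockQ is the mean over reference interfaces.
- **GDT_TS** — per chain, `25 × Σ_t f(t)` over t ∈ {1, 2, 4, 8} Å, with f(t)
  the maximal fraction of CA atoms superposable within t (deterministic
  seed-and-extend search).

**Chain mapping.** Chains map only within identical-sequence groups; the
bijection maximizing the QS-style shared-contact objective is found by
exhaustive permutation search (groups ≤ 6 copies) or greedy assignment with
swap hill-climbing.

**The jury.** Entry (i, j) of a pairwise matrix holds metric(model *i* vs
model *j* as reference); model *i*'s component jury score is its row mean.
Three combination variants:

- *linear* — equal-weight (configurable) mean of `dockq_jury`, `qs_jury`,
  `lddt_jury`, for linear correlation with observed quality;
- *rank* — Borda aggregation of within-ensemble component ranks,
  `rank_score = 1 − (mean_rank − 1)/(n − 1)`, for putting the best model
  first;
- *single* — one model scored against a user-supplied reference model set.

Local (per-residue) estimates are the mean per-residue oligo-lDDT over all
comparisons, written both to a CASP QMODE2 QA file and into the B-factor
column of per-model PDBs (score × 100).

## Worked example

Generate a synthetic A2B2 ensemble with graded noise and rank it:

```sh
oligoqa simulate -s A2B2 -l 12 -n 5 --seed 3 -o models
oligoqa rank -s A2B2 -t T0001 -o results models/model_*.pdb
cat results/ranking.tsv
```

```
model	dockq_jury	qs_jury	lddt_jury	combined	rank
model_001	0.345	0.444	0.455	0.667	1
model_002	0.395	0.409	0.434	0.667	2
model_003	0.435	0.341	0.359	0.667	3
model_004	0.349	0.304	0.281	0.250	4
model_005	0.419	0.274	0.239	0.250	5
```

The decoys were generated with increasing noise, so `model_001` is truly the
best — and the jury ranks it first without ever seeing the reference: its
similarity to the rest of the ensemble (`qs_jury` 0.444, `lddt_jury` 0.455)
is the highest. `combined` is the Borda rank score (ties share a value and
are broken by the linear score). `results/T0001.qa` holds the same ranking in
QMODE2 form with per-residue local scores, and each
`results/model_*_local.pdb` carries those local scores in its B-factor
column.

Direct evaluation against a known reference:

```sh
oligoqa compare models/model_001.pdb models/reference.pdb -o cmp
```

```
Model model_001 vs reference reference
  chain mapping: A:A,B:B,C:C,D:D
  oligo_lddt       1.000
  qs               0.965
  dockq_mean       0.965
  dockq_AB         0.928
  ...
  gdt_ts_A         100.00
  rmsd_ca_A        0.155
```

Here the mildly perturbed model keeps essentially perfect per-chain folds
(GDT_TS 100, CA RMSD 0.16 Å) and near-native interfaces (QS 0.965).

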
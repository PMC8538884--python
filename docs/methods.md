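# Methods

## The data model

The central object is a species × gene-family matrix of non-negative
integer copy numbers, optionally paired with each species' total gene
count. Family identifiers are opaque strings (no validation against any
ortholog database). The matrix is either read from TSV or aggregated from
per-gene annotation tables in the emapper dialect, where each gene lists
`CLUSTER@TAXID` ortholog-group assignments at several taxonomic depths and
a single taxon scope (e.g. `33090` for Viridiplantae) selects the depth at
which copies are counted.

Pathway summaries treat absence as data: families named in a pathway map
but missing from the matrix are materialized as all-zero columns rather
than dropped, because the absence of a pathway family in a clade is exactly
the kind of signal these displays exist to show. A family listed under two
pathway entries is counted once in the pathway-to-genome ratio (and appears
once in the subset matrix, at its first listing position, with a logged
warning) — double counting would inflate the ratio of species carrying the
shared family.

## Labeling

`label[s] = 1` iff at least `min_present` (default 2) distinct marker
families are present (count ≥ 1) in species `s`. "Distinct clusters, not
total copies" is the default reading because presence of multiple paralog
*clusters* indicates retained duplications older than the species, whereas
copy inflation within one cluster can be a recent, lineage-private event.
The alternative reading (summed copies ≥ threshold) is available via
`mode="count_copies"`. Species lacking all marker columns are labeled 0,
not dropped. Labels are invariant to multiplying all counts by a positive
integer, and adding a present marker can only turn a 0 into a 1.

## Feature mining

Learners see the normalized matrix with the marker columns removed: the
label is a deterministic function of the markers, which would otherwise
dominate every fit and tell us nothing new.

* **Normalization.** Default `per_family_max` (each column divided by its
  maximum over species; all-zero columns stay zero), which makes
  copy-number patterns comparable family by family regardless of absolute
  family size. `per_species_total` (counts as genome fractions) is the
  alternative; raw counts can be passed directly.
* **Evaluation protocol.** Accuracy/AUC distributions over repeated
  trainings are only meaningful with resampled evaluation, so the default
  is a stratified 75/25 train/test split per iteration, scored on the
  held-out fold. A resubstitution mode (train = test = all species) exists
  for comparison; it is not the default and its scores are optimistically
  biased.
* **Importance.** Normalized impurity decrease from a 500-tree forest
  (unlimited depth, sqrt-of-features per split — the standard defaults,
  recorded in the run manifest). Each iteration's importances sum to 1
  whenever the forest splits at all; a constant feature gets exactly 0.
  Permutation importance on the held-out fold is available as an option.
  Selection takes the k families with the largest mean importance over
  iterations; ties break alphabetically for determinism.
* **Ridge baseline.** A ridge-penalized linear classifier (regularization
  strength 1.0) on standardized features, ranked by |coefficient|. Kept as
  the linear point of comparison; on copy-number data its coefficients
  spread over correlated families and rarely single out a clean top set.
* **Permutation null.** The null arm re-permutes the label vector uniformly
  at every iteration, preserving the class imbalance (Bernoulli resampling
  would change the marginal and is deliberately not offered). Both arms use
  the identical split/fit/score protocol and seeds. The reported p-value is
  the add-one estimator `(1 + #{null ≥ observed}) / (1 + n)`, which is
  never exactly zero. If a split ever produced a one-class fold (impossible
  under stratification with ≥ 2 members per class), it is redrawn with an
  offset seed and logged, keeping the protocol total.
* **Determinism.** Iteration `t` seeds its split and forest with
  `base_seed + t`; identical configs give bit-identical importance matrices
  and performance vectors.

### What calibration on null data does and does not pin down

On signal-free data the permuted-label arm is well calibrated per matrix
(mean AUC ≈ 0.5, mean accuracy ≈ the test-fold majority-class frequency),
because each iteration draws a fresh permutation. The true-label arm on a
*fixed* matrix is a different matter: whatever spurious feature–label
correlations that one matrix happens to contain are shared by the train and
test folds of every split, so its mean AUC over iterations deviates from
0.5 by a matrix-level offset (empirically sd ≈ 0.07 at 40 species, whether
20 or 500 features are in play). Chance-level calibration of the true arm
is therefore a statement about the average over replicate matrices, and the
calibration checks in the test suite and acceptance script average 200
iterations over 10 independently simulated signal-free matrices. This is
also why the permutation null — not a "train on noise" control — is the
right yardstick for a selected feature set on real data.

## Alignment rarity

For an alignment of `N` sequences, each non-gap cell of sequence `s` at
column `p` scores `N − count(s, p)` where `count` is the number of
sequences (including `s`) with the same residue at `p`. Gap handling:
a gapped cell scores 0 and a gapped sequence is excluded from the column's
match counts. `N` is the alignment size, not the per-column non-gap depth;
the per-column variant is available (`per_column_n=True`) and is the one to
prefer when gap content differs wildly between sequences, since under the
default a sequence gains `N − count` rarity merely because others are
gapped. Per-sequence totals (no length normalization by default; an option
divides by non-gap length) rank sequences, ties alphabetically; per-cell
vectors are emitted for bar plots. Positions are 1-based in output files,
0-based internally.

## Synthetic data

`simulate_matrix` emulates an ortholog-cluster count table at desk scale:

* **Background counts** are zero-inflated negative binomial, defaults
  π₀ = 0.3, μ = 2, dispersion k = 1 — sparse, overdispersed, with
  occasional large bursts, matching the texture of real copy-number tables
  (many absences, rare dozens-of-inparalogs clusters).
* **Markers and labels.** A configurable fraction (default 0.25) of species
  is drawn to be class 1 and given ≥ `min_present` distinct marker clusters;
  class-0 species get fewer. Labels recomputed from the emitted matrix by
  the labeling rule equal the emitted truth exactly, by construction.
* **Signal families** are a background draw plus an additive shift Δ
  (default +3 copies) in class-1 species. Additive-on-counts is the
  simplest planted effect with an unambiguous recovery criterion.
* Species are i.i.d. — there is **no phylogenetic correlation** between
  them. Real species share ancestry, so real matrices contain correlated
  blocks that make labels partially predictable from clade membership
  alone; passing recovery tests here shows the machinery works under clean
  conditions, not that it separates trait-linked from clade-linked families
  in real data. Tree-structured simulation is out of scope.

`simulate_alignment` draws a random consensus, mutates background sequences
at a low per-site rate and one designated sequence at an elevated rate
toward non-consensus residues, with optional uniform gaps. When the rates
are equal the designated sequence is exchangeable with the rest (checked as
a calibration property); there is no named substitution model or indel
process.

## Problem sizes used in the checks

The benchmark studies run at 40 species × ~510 families with 200-tree
forests: 50 importance iterations per study for selection (mean importance
is stable well before 50 iterations at this size) and 200 iterations for
the true-vs-null comparison; planted-family recovery is assessed over five
independent studies. The library defaults (1000 iterations, 500 trees)
remain the recommendation for real analyses; the study sizes are the
package's own choice of a desk-scale benchmark with adequate power — the
planted effect (Δ = +3 on a μ = 2 background) is large enough that recovery
of ≥ 8/10 planted families is expected at these sizes.

## Numerical and degenerate-input choices

* Count-matrix parsing is strict: duplicate IDs, negative or non-integer
  cells are hard errors naming the offender; a header-only file is a valid
  0-species matrix.
* `per_family_max` normalization maps all-zero columns to zero (never NaN).
* Heatmap leaf ordering is average-linkage (UPGMA) agglomeration on
  Euclidean distances — the common heatmap default — computed directly with
  scipy's deterministic linkage; a single row/column yields the trivial
  order.
* Alignments must use `-` gaps; `.` is rejected rather than silently
  reinterpreted, since mixed gap dialects usually indicate a format
  mismatch.
* Single-class label vectors are a hard error for every learner; the
  class-balance summary warns when a class is empty.

## Known limitations

* No downloading or querying of ortholog/pathway databases; annotation
  tables and pathway maps are inputs.
* No phylogenetic tree inference, and no correction for phylogenetic
  non-independence in the mining step — importances conflate trait-linked
  and clade-linked families when the label is phylogenetically clustered.
* No hyperparameter search; only the ridge and random-forest learners.
* The permutation p-value's resolution is bounded by the iteration count
  (minimum `1/(n+1)`).
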
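# Methods

This note documents the models and procedures implemented in
`metalsite`, the parameters that matter, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Problem and data model

Fe and Cu centers in electron-transport proteins are coordinated almost
exclusively by cysteine and histidine side chains, so the prediction
task is residue-level binary classification restricted to C and H.
Every C (or H) in a sequence is a candidate site; a site is positive iff
its 1-based position carries an experimental metal-binding annotation.
Separate models are fitted per residue type, and the negative set of
each model consists of non-binding residues of the *same* type
(non-binding cysteines for the cysteine model), which is what makes the
class ratios of a curated benchmark meaningful (e.g. 79 binding vs 112
non-binding cysteines, 77 vs 256 histidines on a 44-protein training
set).

Annotations whose residue letter disagrees with the sequence are
rejected row-by-row with a report; annotations on residues other than
C/H are skipped rather than fatal, because the method is undefined for
them.  Coordinates are 1-based in every file; internally, window
positions are center-relative offsets in [−w, +w].

## Window encodings

Each site is represented by its `2w+1`-residue context (default w = 6,
window 13).  Overhangs past either terminus are padded with `X`, and an
encoder maps every window position to a 20-vector in PSI-BLAST column
order (A R N D C Q E G H I L K M F P S T W Y V), giving a 260-element
base feature vector:

* **AA** — one-hot identity.
* **BLOSUM62 / PAM250** — the residue's row of the substitution matrix
  (Biopython's published tables), min–max rescaled to [0, 1] over the
  whole 20×20 matrix so all encodings share a range.  The sources this
  encoding family comes from state no scaling; a global affine map is
  the choice that preserves the matrix's relative structure.
* **PSSM** — the profile row of the corresponding sequence position,
  each log-odds score squashed by the logistic 1/(1+e^(−x)).  The
  logistic is the standard squashing for profile encodings and is
  strictly increasing, so within-position score order is preserved; it
  is exposed as a configuration hook rather than hard-wired.

Padding positions contribute an exact all-zero row under every encoding
— distinguishable from any real residue (the logistic never reaches 0)
and contributing nothing to kernel distances.

The PSSM parser reads the ASCII matrix of PSI-BLAST's
`-out_ascii_pssm`: it keeps the first 20 numeric columns per row (the
log-odds block), ignores the trailing weighted-percentage block and the
Lambda/K footer, and reports truncated or non-numeric rows with their
line number.  Whether weighted percentages would serve equally is
untested here; log-odds are the standard choice for profile encodings.

## Significant amino-acid pairs

For windows of one center type, every canonical pair
(offset₁ < offset₂, both ≠ 0, padding excluded) of residue assignments
is counted by window membership: `n` windows contain the pair, `x` of
them are positive, out of `N` windows with `M` positives.  The center
offset is excluded because it is constant within a model's dataset;
counting is 0/1 per window, not occurrence multiplicity.

Enrichment is scored with the hypergeometric distribution.  The
point-mass C(M,x)·C(N−M,n−x)/C(N,n) is computed in log-space (lgamma);
the p-value is the upper-tail sum Σ_{i≥x}, the probability of enrichment
at least as extreme under random label assignment — the standard reading
of a "significant" pair.  The point-mass variant is available behind a
flag since published per-pair values cannot be attributed to one
convention without their counts.  Pairs with p < α (default 0.05 — a
conventional level consistent with the largest values appearing in
published pair tables, ~1.9×10⁻²) are ranked ascending by p with a
deterministic lexicographic tie-break.  No multiple-testing correction
is applied, matching the procedure this reimplements; the forward
selection stage is what controls how many ranked pairs actually enter
the model.

Selected pairs enter the classifier as binary indicator features
appended to the 260-vector.

## RBF network

The classifier is a Gaussian radial-basis-function network using *all*
training vectors as centers with one fixed bandwidth:

    g_j(x) = Σ_i  w_ij · exp(−‖x − μ_i‖² / (2σ²)),   j ∈ {binding, non-binding}

* **Bandwidth σ = 5** by default.  "Bandwidth 5" is read as σ in
  exp(−r²/2σ²); since kernel conventions differ between packages, σ is a
  first-class parameter rather than a constant.
* **Weights** solve the ridge least-squares system
  (ΦᵀΦ + λI)W = ΦᵀT with one-hot targets T.  The all-centers design
  matrix Φ is square and can be ill-conditioned, hence the default
  stabilizer λ = 1e−8; λ = 0 is supported and then the minimum-norm
  least-squares solution is used, which interpolates the targets exactly
  on distinct, numerically well-posed training sets.  Note that for very
  smooth configurations (few dimensions, σ much larger than the point
  spacing) the kernel matrix is singular beyond double precision and no
  solver interpolates; the interpolation guarantee is a property of
  well-posed systems.
* **Decision**: argmax over the two output nodes; an exact tie resolves
  to non-binding, the conservative choice for a screening tool.
* **Persistence**: a JSON archive (format-versioned) holding centers,
  weights, σ, λ and the feature specification (encoding, w, SAAP list,
  training accessions).  Python's float repr makes the round-trip
  bit-exact.

Degenerate inputs: single-class training sets and non-finite features
are rejected; duplicated points with conflicting labels train fine with
λ > 0 and produce tied (→ non-binding) outputs at the duplicate.

## Evaluation protocol

* **Cross-validation**: stratified k-fold (default 10) at residue level
  with a recorded seed; fold sizes differ by at most one per class.
  Whether the protocol this follows stratified at residue or protein
  level is not documented; residue-level stratified is the default here.
  Predictions are pooled over folds into a single confusion matrix.
* **SAAP hygiene**: by default mining and ranking are re-run inside each
  training split, so the test fold never influences which pairs exist
  (`SaapConfig(mode="per_fold")`).  Mining once on the full dataset
  before CV — the classical but leaky protocol — is an explicit mode
  (`mode="fixed"`), kept for reproducing that practice.
* **Forward selection** scans prefixes of the ranked catalog, recording
  pooled CV accuracy after each addition; k* is the accuracy-maximizing
  prefix with ties to the smallest k (k* = 0 keeps base features).
  Since one added indicator changes any pairwise squared distance by at
  most 1, the kernel matrix is updated incrementally instead of being
  rebuilt, which makes the scan linear in catalog length.  A
  `max_features` cap (default: no cap) bounds the scan; the package's
  own benchmark runs scan the top 30 ranked pairs, since informative
  pairs concentrate at the head of the ranking.
* **`MetalSiteModel.fit`** combines the two: the catalog is mined and
  ranked once on the training data, forward selection picks k*, and the
  reported CV counts come from a leak-free run that re-mines per fold
  and keeps its top k* pairs (the global ranking influences only the
  choice of k*).  `leak_free=False` reuses the global list per fold.
* **Independent test**: a trained model carries its training accessions;
  evaluation on held-out proteins errors out if any accession overlaps.
* **Metrics**: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
  TP/(TP+FP), accuracy (TP+TN)/total, MCC
  (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Zero denominators
  produce an explicit `undefined` flag, never a silent 0.  Display
  rounding is one decimal for percentages and two for MCC; full
  precision is kept internally.  (One published reference row,
  22/4/25/0, prints 92.3% accuracy; the arithmetic gives 47/51 = 92.2%,
  which is what this package reports.)

## Synthetic benchmark

The generator emulates exactly the structure the method exploits:

* i.i.d. background residues (uniform over 20 letters by default,
  arbitrary frequencies configurable);
* candidate centers planted on a non-overlapping grid (spacing 2w+1),
  shuffled and dealt into `n_positive_sites` annotated and
  `n_negative_sites` unannotated centers (defaults 60 / 200 across 24
  proteins of length 120–240, mirroring the few-fold negative excess of
  curated benchmarks; incidental background C/H become extra negatives,
  as in real sequences);
* one planted pair, (−4C, +1P), carried with probability 0.8 by positive
  windows and 0.05 by designated negatives.  A single pair is the
  default because independently planting several pairs on the same
  sites makes *composite* pairs (one member from each) genuinely
  enriched, so "the planted pair ranks first" stops being a meaningful
  recovery criterion;
* profiles = rounded Gaussian noise (sd 1) everywhere, plus a log-odds
  bump of round(2·`pssm_signal`) on the realized residue at
  positive-window positions, applied with probability 0.6 per position
  to mimic partial conservation.  `pssm_signal = 0` yields profiles
  independent of the labels, hence uninformative.

Every run is reproducible byte-for-byte from its seed, and a JSON-lines
manifest records each planted decision.

**What passing tests show** — that mining recovers a planted enrichment,
that selection keeps it, that the network separates profile+pair signal
of this strength, and that nothing fires when no signal is planted.
**What they do not show** — performance on real proteins: the generator
has no homology between sequences, no realistic residue composition, no
correlated profile columns, and its negatives are drawn from the same
background as the positives' flanks.  Published cross-validation
figures on curated protein data (~93% accuracy) are therefore *not*
targets for the synthetic benchmark; the metric arithmetic on their
confusion rows is verified exactly instead.

Null calibration details: the uniformity check of the pair p-value uses
pair probability 0.3 (fine-grained hypergeometric support), a background
excluding the center letter so that every window is a planted slot (the
label-permutation null then holds exactly; incidental centers would
dilute N and bias x upward), and the randomized-PIT transform
p′ = p − U·pmf(x), the exact uniformization of a discrete upper-tail
p-value, before the Kolmogorov–Smirnov comparison.  The raw p-values are
asserted super-uniform (ECDF(t) ≤ t up to sampling noise), which is the
defining property of a valid conservative p-value.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on the
default generator (≈520–540 cysteine sites) over 20 and 5 seeds
respectively, scan the top 30 ranked pairs in forward selection, verify
the hypergeometric tail exhaustively for all ~46k valid parameter sets
with N ≤ 30 against exact rational arithmetic, and use 100 random
instances for the interpolation check.  These sizes were chosen so the
whole battery completes in a few minutes on one CPU while keeping every
statistical assertion comfortably powered.

## Known limitations

* The logistic PSSM scaling and the σ-inside-the-exponent bandwidth
  convention are documented assumptions with configuration hooks, not
  verified against the original implementations.
* Dataset construction from UniProt with BLAST-based 20%-identity
  culling is out of scope (it needs external services); the readers
  accept any FASTA + annotation TSV produced by such a recipe.
* Only pairwise residue co-occurrence is mined; higher-order tuples are
  not.
* k* from forward selection depends on the CV split seed; the audit
  trail of (k, accuracy) is returned so that sensitivity to the split
  can be inspected.
* Sites closer than a window to each other are encoded independently;
  a window overlapping a second annotated site carries no special
  treatment.
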
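# Methods

This package predicts drug–target interactions (DTIs) from two
precomputed representations — an evolutionary profile per protein and a
substructure fingerprint per drug — with a Rotation Forest ensemble.
This note records the model, the numerical conventions, and the design
choices made where the construction was genuinely open.

## Protein representation

A protein of length P is represented by its PSI-BLAST position-specific
scoring matrix (PSSM): a P×20 grid of integer log-odds scores, row i
giving the propensity of residue i to mutate into each of the 20
standard amino acids. The parser consumes the `-out_ascii_pssm` dialect,
keeps only the first 20 numeric columns (the log-odds block), and
re-orders columns to the fixed PSI-BLAST header alphabet
`ARNDCQEGHILKMFPSTWYV`, so every profile is column-aligned regardless of
file dialect. Scores are used raw by default; an opt-in elementwise
sigmoid (1/(1+e^(−x))) is available (`normalize="sigmoid"`) since no
normalisation convention is canonical for this descriptor. Generating
PSSMs (PSI-BLAST vs SwissProt, e-value 0.001, 3 iterations) is the
user's job; the package only parses the output.

## Dual-tree complex wavelet transform

The 2-D transform runs four real, separable wavelet filter-bank trees in
parallel (two per axis). Stage 1 uses a near-symmetric biorthogonal
13/19-tap pair; the second tree's stage-1 filters are the first tree's
delayed by one sample. Levels ≥ 2 use a 14-tap orthonormal Q-shift pair:
one tree filters with `h`, the other with its time reverse, so group
delays straddle the half-sample offset and the recombined coefficients
are approximately analytic. Per level the four oriented real subbands
are combined by the unitary sum/difference pairing (±, divided by √2)
into six complex subbands at +15°, +45°, +75°, −15°, −45°, −75°; the
assignment of tree combinations to signed orientations was fixed once by
measuring grating responses and is frozen in code.

Numerical conventions:

* **Filters.** All lowpass filters sum to √2. The 13-tap stage-1 lowpass
  is a table of exact rationals (denominator 5120); its 19-tap complement
  is derived at import by solving the half-band linear system with two
  vanishing moments, so perfect reconstruction of the stage-1 pair holds
  to ~1e−15 rather than to published rounding. The Q-shift table is
  projected onto exact orthonormality, DC gain √2 and a Nyquist zero
  (taps move < 2e−8 from the published values).
* **Boundaries.** Symmetric (half-sample) extension, realised by
  reflecting the input into a doubled periodic domain. On that domain
  every decimating level is an exactly orthogonal operator, and with the
  decimation phase fixed at half the filter length the two trees of each
  axis are exact mirror images; stored subbands are cropped to the
  nominal decimated sizes and the mirrored halves are re-materialised
  exactly during inversion. Net effect: symmetric-extension semantics
  with machine-precision invertibility (reconstruction error ~1e−15,
  versus the 1e−8 tolerance asserted in tests).
* **Sizes.** Inputs are edge-replicated up front to a multiple of 2^J on
  both axes (the doubled domain must stay even through J halvings);
  the inverse crops back. Both axes must be ≥ 2^J.
* **Diagnostics.** Level-2 subband energy changes by < 5% under a
  one-sample circular shift (a single-tree DWT with the same filters
  fails this bound in median and varies by multiples, not percent,
  across impulse positions);
  an oriented grating concentrates > 50% of high-pass energy in its own
  ±θ family. These two properties — near shift invariance and
  directional selectivity — are the reason this transform is used over
  an ordinary DWT.

## The 256-dimensional protein descriptor

Only the *count* of the final descriptor is fixed by convention (256);
the reduction from variable-size subbands to that count is this
package's own declared scheme, chosen to be length-independent and
deterministic:

* profiles shorter than 8 rows are reflected up to 8, then reflected to
  the next multiple of 2^J (J = 2 by default);
* each of the 12 high-pass subbands (2 levels × 6 orientations) is
  reduced to a 4×5 grid by adaptive average pooling of coefficient
  magnitudes → 240 features;
* the four level-2 low-pass images are averaged, divided by 2^J (so a
  constant profile of value c gives low-pass features ≈ c), column
  averaged and pooled to 16 row bins → 16 features;
* concatenation order: level 1 orientations (+15, +45, +75, −15, −45,
  −75) row-major, then level 2, then the low-pass bins.

J = 2 is the default because 2 levels × 6 orientations gives the
natural 240+16 split; deeper levels would collapse the 20-column axis
below the filter length. Because the original authors' reduction is
unpublished, absolute feature values — and therefore headline accuracies
on the gold-standard benchmarks — are not expected to reproduce
digit-for-digit; the structural and behavioural properties above are
what this implementation pins down.

## Drug representation

Each drug is an 881-bit PubChem substructure fingerprint, consumed
precomputed (one 0/1 string or 881 delimited tokens per row). Bit
semantics are opaque to the pipeline. A pair descriptor is the
concatenation fingerprint-then-protein-features: 881 + 256 = 1137
columns.

## Rotation Forest

Each of L members: permute the F features; split into K contiguous
subsets (first F mod K subsets one larger); per subset choose a random
non-empty class group (each class kept with probability 0.5), subsample
75% of those classes' rows without replacement, run covariance PCA on
the subsample restricted to the subset's features and keep *all*
loadings (rotation, not reduction; rank-deficient samples are completed
to a full orthonormal basis by the remaining right-singular vectors);
assemble the loadings block-diagonally into a sparse F×F rotation —
orthonormal, hence distance-preserving — and fit one CART (Gini,
unlimited depth) tree on the fully rotated training matrix. Prediction
averages member confidences; the label is the argmax with exact ties
going to the negative class. Defaults K = 30, L = 17, the values a
grid search over the (K, L) accuracy surface favours for this
descriptor (a `grid_search` utility is provided to recompute such a
surface). Subsampling without replacement (rather
than a with-replacement bootstrap) is chosen so that a fraction of 1
degenerates exactly to full-data PCA — the reduction the test suite
verifies. All randomness flows from one seed through spawned
`SeedSequence` children; training is bit-reproducible.

## Evaluation

Negatives are drawn uniformly without replacement from the complement
of the known positives in the drug×protein grid, once per dataset
(matching the robustness-study design; per-fold redraw would change the
question being asked). A balanced draw equals the positive count. The
undiscovered-interaction contamination this implies is accepted: at
gold-standard scale the complement outnumbers positives ~28:1.

Metrics per fold: ACC = (TP+TN)/total, PR = TP/(TP+FP),
Sen = TP/(FN+TP), MCC = (TP·TN − FN·FP)/√((TN+FN)(FN+TP)(TP+FP)(FP+TN)),
plus trapezoidal AUC over the tie-grouped threshold-sweep ROC. A metric
with zero denominator is reported as 0 with a warning flag rather than
raising, so small-fold reports stay comparable. Cross-validation is
stratified (plain random splitting can produce one-class folds on the
smallest collections) with seeded shuffling; reports carry per-fold
rows and the mean ± sd aggregation.

## Synthetic worlds

The generator fabricates all three inputs with a known planted signal.
Drugs and proteins carry latent vectors u_d, v_p ∈ R^k drawn N(1, I);
a pair interacts with probability σ(s·⟨u_d,v_p⟩/√k + b), b solved by
root-finding so the expected positive fraction equals `positive_rate`.
Fingerprint bits are noisy sign readouts of random projections of u_d;
PSSMs are AR(1)-smoothed (ρ = 0.7) integer profiles in [−10, 12]
modulated by smooth row×column patterns with amplitudes v_p, so both
halves of the descriptor carry signal and ablations can attribute
performance per modality. Defaults: 60 drugs × 50 proteins, k = 2,
latent mean 1, s = 3, positive rate 0.1 (~300 positives, ~600 rows) —
sized near the smaller gold-standard collections so a full 5-fold CV
runs in well under a minute.

The unit latent mean matters: with zero-mean latents the pure bilinear
logit is nearly invisible to axis-aligned tree splits at this sample
size (tree ensembles given the *true* latent vectors stay well short
of the Bayes-optimal ranking), whereas the mean shift contributes
additive main effects — interpretable as a dominant druggability/promiscuity axis —
that tree ensembles recover, while the pairwise term keeps the problem
genuinely relational. What passing tests show, therefore, is that the
pipeline reads real signal out of both modalities and collapses to
chance under label permutation or zero signal strength; they do not
show that gold-standard chemistry or real evolutionary profiles are
modelled faithfully (fingerprint bits here are dense random readouts,
not substructure chemistry; PSSM patterns are smooth modulations, not
phylogeny).

## Known limitations

* Binary classification only; the data model carries class lists but
  multi-class behaviour is untested.
* The 256-feature reduction is this package's convention (see above);
  cross-package numerical comparison of descriptor values is not
  meaningful.
* `predict` confidences are ensemble vote averages, not calibrated
  probabilities.
* The transform stores four low-pass tree images and six complex bands
  per level (the usual 4× redundancy of the 2-D dual tree); memory is
  ~8× the input for J = 2, irrelevant at PSSM sizes but worth knowing
  for large images.
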
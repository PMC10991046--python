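# Methods

This note documents the statistical model, the algorithmic and numerical
choices behind `triadkit`, what the synthetic-data generators do and do
not emulate, and the limitations a user should keep in mind.

## Measurement model

Responses are dichotomous (correct/incorrect, missing allowed). The
response function is the three-parameter logistic

P(x = 1 | θ) = c + (1 − c) · logistic(α (θ − β)),

evaluable everywhere in the package for any valid (β, α > 0, 0 ≤ c < 1).
Only the Rasch restriction (α ≡ 1, c ≡ 0) is ever *estimated*: it is the
simplest model on which difficulty and ability share a scale, and a 3-AFC
format already suppresses the response-bias problems that motivate richer
parameterizations. Estimating slopes or guessing asymptotes is out of
scope; banks with non-default α or c can still be scored and their
information curves computed.

### Calibration

`fit_rasch` maximizes the marginal likelihood under a fixed N(0, 1)
latent prior by EM:

- **Identification.** The prior fixes location and scale, so average
  ability is 0 by construction and every respondent — including
  all-correct and all-incorrect patterns — receives a finite estimate.
- **Quadrature.** Fixed rectangular grid of 61 nodes on [−6, 6] with
  normalized normal weights. Deterministic, and ample resolution for
  |θ| ≤ 4; the node count, span, tolerance and iteration cap are all
  settable through `CalibrationConfig`.
- **E-step.** Posterior over nodes per respondent; missing responses are
  treated as ignorable and simply drop out of the likelihood, which is
  what permits scoring respondents who answered only a subset of a bank.
- **M-step.** For each item the expected score equation
  Σ_q n_jq · logistic(θ_q − β_j) = r_j is strictly decreasing in β_j, so
  it is solved by bracketed root finding on [−6, 6] (no step-size or
  starting-point sensitivity).
- **Convergence.** Stop when the largest |Δβ| falls below 1e−4 (default)
  or after 500 iterations. The marginal log-likelihood trace is stored in
  the bank's `calibration_meta` and is non-decreasing by construction of
  EM; tests assert this on every run they make.
- **Degenerate items.** An item answered identically by everyone has no
  finite maximum-likelihood difficulty. Its β is clamped to ±6 with a
  warning and the item is listed in `calibration_meta["degenerate_items"]`,
  keeping banks serializable.

### Scoring

Abilities are expected a posteriori (EAP) means with posterior SDs as
standard errors, both at calibration time and when projecting new
respondents onto a fixed bank (`score_with_fixed_items`). EAP was chosen
over maximum-likelihood scoring because it is finite on perfect response
patterns and shrinks gracefully when few items are answered; the shrinkage
toward 0 means extreme abilities are mildly underestimated, which users
comparing groups should remember. Scoring a subset of a bank's items
yields estimates on the same scale as full-bank scoring because the item
parameters, prior and quadrature are identical.

### Information and fit

Test information sums item Fisher information
α² ((P − c)/(1 − c))² (1 − P)/P (which is P(1 − P) for Rasch items), and
SE(θ) = 1/√I(θ) pointwise. AIC and BIC follow from the marginal
log-likelihood with the number of free parameters equal to the number of
item difficulties. RMSEA uses an M2-type limited-information statistic:
residuals between observed and model-implied first- and second-order
margins, weighted by the inverse model-implied covariance of the margin
indicators with the parameter Jacobian projected out; RMSEA =
√(max(M2 − df, 0)/(df · N)) with df = (#margins − #parameters). The
margin covariance matrix grows quadratically in the number of item pairs,
so RMSEA is computed only for complete-response matrices of at most 40
items by default (configurable); beyond that, and with missing data, the
field is `None` with an explanatory note rather than approximated by an
unrelated quantity. A value at or below 0.06 is documented as good fit.

### Dimensionality

`dimensionality_scree` eigendecomposes the inter-item Pearson correlation
matrix (pairwise-complete) and calls data unidimensional when the
first-to-second eigenvalue ratio exceeds 3 (configurable). Pearson
correlations of binary items understate the latent correlations, so the
ratio is conservative; at realistic bank sizes (tens to hundreds of
items) single-trait data clears the threshold comfortably, while for very
short tests (~20 items) the ratio can sit below 3 even for single-trait
data — the threshold, not the eigenstructure, is the limitation there.

## Triad screening

`build_triads` implements the confusability screen: cross-identity image
pairs (optionally demographically yoked) are ranked by similarity; each
identity retains only its highest-similarity cross pair; each retained
pair is completed by the least-similar same-identity partner of whichever
side coheres worst. Triads therefore pair the most confusable
different-identity images with the least cohesive same-identity images.

Choices where the procedure is underdetermined:

- **Similarity metric.** Cosine over feature vectors by default (negated
  Euclidean distance available). Descriptor-based screens are insensitive
  to this choice when embeddings are roughly norm-equalized.
- **Tie-breaks.** Equal similarities resolve to the lexicographically
  smallest image-id pair, everywhere; the screen is therefore a pure
  function of its inputs and invariant to input row order.
- **Deduplication.** "One cross pair per identity" is read as per-identity
  deduplication: one triad at most per retained pair, with identities free
  to reappear as odd images elsewhere unless the `disjoint` flag is set.
  Other readings exist; this one is deterministic and matches a pool in
  which identities legitimately recur.
- **Observer.** The algorithm-as-observer simulation answers by declaring
  the two most similar images the same identity. On screened triads it
  performs far below the 1/3 chance level *by design* — the screen selects
  exactly the items the embedding fails — which is the intended evidence
  that the items cannot be solved from the embedding that built them.

## Subset assembly

Graded subsets: rank by difficulty, median split (odd counts send the
median item to the easy half, configurable), sample uniformly without
replacement within each half. Parallel subsets: either exclude the
easiest items and sample uniformly from the remainder, or union matched
easy/difficult graded subsets. Leftover items are reported explicitly in
every plan's recipe. Uniform sampling equalizes subset difficulty only in
expectation: for a 225-item bank with difficulty SD ≈ 1.6, the SD of the
difference between two 75-item subset means is ≈ 0.25, so individual
draws can differ by several tenths of a logit while the across-seed mean
gap stays well under 0.25. No optimization or stratification finer than
the median split is attempted (deliberately out of scope).

`subset_summary` reports population-SD (ddof = 0) difficulty summaries so
a singleton subset has SD 0.

## Variance decomposition

σ²_session = σ²_session+test − σ²_test, always subtracted on the variance
scale. The default convention interprets scalar inputs as SDs and returns
an SD, because that is how retest dispersions are usually printed; list
inputs are reduced to sample SDs (n − 1). A negative solved variance is
returned signed with a diagnostic flag (and a NaN SD) — it indicates the
additive noise model is violated or sampling error dominates, and should
be shown, not clipped.

## Synthetic data: what it does and does not emulate

`simulate_responses` draws abilities from a normal population (default
N(0, 1)) and difficulties uniformly on [−3.8, 1.7] — the span a
well-constructed confusable-triad bank occupies — and samples each cell
independently from the response model. Default experiment sizes mirror a
realistic norming study (about 200 respondents by 225 items), which runs
in seconds. One `SeedSequence`-spawned stream per stage (abilities, bank,
responses) makes every experiment a pure function of its design.

Because the generator *is* the fitted model, recovery and transfer
results demonstrate internal consistency of the estimation machinery —
identifiability, convergence, scale anchoring, subset-scoring coherence —
not robustness to real-data features. Real response matrices carry local
dependence between triads sharing identities, slope variation across
items, speed-accuracy trade-offs, fatigue and learning drift; none are
simulated, so passing tests bound implementation error, not model
misspecification. Similarly, `make_synthetic_embeddings` (paired Gaussian
identity clusters on the unit sphere, with a confusability parameter that
pulls paired centroids together) reproduces the *geometry* the screen
exploits, not the statistics of any particular face-embedding network.

## Known limitations

- Only Rasch difficulties are estimated; 2PL/3PL calibration,
  multidimensional and polytomous models, and adaptive testing are out of
  scope.
- RMSEA is unavailable for incomplete matrices and very large banks (see
  above); AIC/BIC remain available everywhere.
- EAP shrinkage biases extreme abilities toward 0; with very short
  subsets the effect is visible in subset-vs-full comparisons as a slope
  below 1 (the correlation, which tests use, is unaffected).
- The scree heuristic is a screen, not a test; borderline ratios deserve
  a proper factor-analytic follow-up outside this package.
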
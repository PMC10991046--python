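# triadkit

Toolkit for building and scoring **calibrated perceptual proficiency
tests** based on three-alternative forced-choice (3-AFC) "odd-one-out"
triads — the design used to measure face-identification proficiency in
forensic and research settings, where examiners must be assessed
repeatedly over time without ever reusing a stimulus.

It is aimed at researchers and practitioners who need to

- **construct maximally confusable triad items** from an identity-labeled
  image embedding or similarity matrix (two images of one identity plus
  one look-alike image of another, demographically yoked so race/gender
  cues cannot solve the item);
- **calibrate item difficulty** and respondent ability on a common latent
  scale with a Rasch model fitted by marginal-maximum-likelihood EM;
- **assemble item subsets** of graded (easy/difficult) or equal
  difficulty, so proficiency can be retested across sessions without
  familiarity inflating scores;
- **score new respondents** against a fixed calibrated bank, and
- **decompose retest score variability** into test-change and
  session-change components.

## The model

The probability that respondent *i* answers item *j* correctly is

    P(x_ij = 1 | θ_i) = c_j + (1 − c_j) · logistic(α_j (θ_i − β_j))

with ability θ, difficulty β, slope α and guessing asymptote c on one
latent logit scale. Calibration uses the Rasch restriction (α = 1,
c = 0): difficulties are estimated by marginal maximum likelihood with a
standard-normal latent prior (EM over a fixed 61-node quadrature), which
anchors average ability at 0. Abilities are posterior means (EAP) with
posterior-SD standard errors — finite even for all-correct patterns.
Measurement precision is summarized by the test information function
I(θ) = Σ_j P_j(1 − P_j), with SE(θ) = 1/√I(θ); model fit by AIC, BIC and
an M2-type limited-information RMSEA; dimensionality by a scree check on
the inter-item correlation matrix. Retest variability obeys

    σ²_session = σ²_session+test − σ²_test

on the variance scale (inputs and outputs may be expressed as SDs).

## Worked example

```python
import numpy as np
import triadkit as tk

# 1. screen confusable triads from (synthetic) identity embeddings
images = tk.make_synthetic_embeddings(n_identities=30, seed=5)
similarity = tk.compute_similarity(images)
triads = tk.build_triads(similarity, images)
observer = tk.simulate_algorithm_observer(triads, similarity)

# 2. calibrate a Rasch bank on a norming sample (here simulated)
design = tk.SimulationDesign(n_respondents=197, n_items=225, seed=11)
responses, true_theta, true_bank = tk.simulate_responses(design)
bank, abilities, stats = tk.fit_rasch(responses)
curve = tk.test_information(bank, np.linspace(-4, 4, 161))

# 3. equal-difficulty 75-item subsets; score one against the full bank
subsets = tk.make_parallel_subsets(bank, n_subsets=2, subset_size=75,
                                   n_exclude_easiest=4, seed=3)
sub = tk.score_with_fixed_items(responses.subset_items(subsets[0].item_ids), bank)
agree = tk.ability_agreement(abilities, sub)

# 4. split retest variability into session and test components
d = tk.variance_decomposition(0.40, 0.31, convention="sd")
```

Output:

```
screened 20 triads; embedding-observer accuracy 0.000 (chance 0.333)
EM converged in 105 iterations, log-likelihood -19834.01
difficulty recovery r = 0.989
difficulty span [-5.08, 1.98]
test information peaks at I = 36.79 (theta = -0.95)
75-item subset vs full-bank ability agreement r = 0.974
session-change dispersion = 0.25
```

Reading the numbers: the screen deliberately selects triads the embedding
itself cannot solve (observer accuracy far below the 0.333 chance level),
so the items are hard for exactly the cue the screen controlled. The
fitted difficulties recover the generating truth (r = 0.989) and the
information curve says this bank measures slightly-below-average ability
most precisely. A 75-item parallel subset reproduces full-bank ability
estimates (r = 0.974), and of the retest spread (SD 0.40 across both a
session and a test change, 0.31 across a test change alone), the
session-only component is SD 0.25.

The same pipeline is scriptable from the shell:

```bash
triadkit simulate --respondents 197 --items 225 --seed 7 --out runs/sim
triadkit fit --responses runs/sim/responses.csv --out runs/fit
triadkit subsets --bank runs/fit/item_bank.csv --strategy exclude-then-sample --out runs/subsets
triadkit score --responses runs/sim/responses.csv --bank runs/fit/item_bank.json --out runs/score
triadkit decompose --sd 0.40 --sd-test 0.31 --out runs/decomp
```

## Layout

| module | contents |
| --- | --- |
| `triadkit.irt` | response function, Rasch MML-EM, EAP scoring, information/SE curves, fit statistics, scree check |
| `triadkit.simulate` | synthetic respondents, guessing baseline, recovery and transfer experiments |
| `triadkit.triads` | similarity computation, triad screening, algorithm-as-observer, synthetic embeddings |
| `triadkit.subsets` | graded and parallel subset assembly, subset summaries |
| `triadkit.reliability` | score agreement, baseline accuracy, variance decomposition |
| `triadkit.io` / `triadkit.cli` | CSV/JSON formats and the `triadkit` command |

See `docs/methods.md` for modeling assumptions, numerical choices and
known limitations.
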
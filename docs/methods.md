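# Methods

## The study design

A *game* is one pair playing `n_rounds = 8` rounds over a shortlist of
`shortlist_size = 10` items drawn uniformly without replacement from a
25-item pool (5 categories × 5 items). Roles alternate every round, so two
consecutive rounds form a *turn* (`turn = ceil(round / 2)`) in which both
players signal every shortlist item once; a seeded coin toss picks the
first signaller. Before rounds 3, 5 and 7 one shortlist item (uniform over
the current roster) is replaced by an unused pool item (uniform), so every
turn after the first introduces exactly one novel item and removed items
never return. The replaced item is drawn without regard to category
balance; nothing downstream conditions on category.

Two derived structures drive the analyses:

- **time-seen** — the number of distinct turns in which a pair has seen an
  item, up to and including the current signal's turn. It is the covariate
  that separates item-specific novelty from game-level fatigue.
- **familiarity chain** — each signal is linked to the signal from the
  immediately preceding turn that it most resembles; within an item's first
  turn the second signal links (forcedly) to the first, and the very first
  signal links to nothing, since there is no precedent to compare against.
  Resemblance ties break to the lower round, then the lexicographically
  smaller signal id, so chains are reproducible. In synthetic mode
  resemblance is the Jaccard similarity of the signals' true tag sets; with
  real data the links are inputs (they were human decisions).

## Perimetric complexity

`PC = (inside perimeter + outside perimeter)² / ink` on a binary ink mask.
Conventions, since the estimator is not uniquely fixed in the literature:

- perimeter is the count of unit pixel edges between foreground and
  background, with pixels outside the canvas counting as background (no
  Crofton/diagonal correction — exactly testable against a brute-force
  exposed-edge count);
- background reachable from the canvas exterior by 4-connected steps is
  *outside*; every other ink/background edge bounds a hole and is *inside*
  (foreground 8-connected, background 4-connected);
- no pre-blurring; greyscale input is thresholded either at a fixed
  intensity or by Otsu's between-class-variance criterion (dark = ink);
- the log transform is the natural log (the base only rescales
  coefficients).

Under these conventions PC is exactly translation invariant and exactly
invariant under nearest-neighbour upsampling. Results on scanned drawings
are comparable across signals in trend, not in absolute value against other
PC implementations.

## Ground similarity

A tagger codes each drawing as a set of canonical labels (trimmed,
uppercased, exact string equality). `JD(X, Y) = 1 − |X∩Y|/|X∪Y|`; two empty
sets are treated as identical grounds (distance 0, logged) since the ratio
is 0/0 there and empty codings are flagged upstream. `JD_μ` for an item is
the unweighted mean JD over all unordered pairs of *first-exposure* signals
— pooled across pairs, because the construct is independence of production;
later-round signals are never pooled in. `JD_μ` is computed per tagger and
then averaged across taggers ("consensus"), not computed on merged tag
sets. Items with fewer than two coded first exposures are excluded with a
logged reason; `n_signals` is reported per item rather than imputed.
Tagger agreement is the Spearman rank correlation of the by-item `JD_μ`
vectors (average ranks for ties; exact permutation p below n = 10, the
t approximation from there).

## The synthetic-data generator

The generator's defaults are the study conditions: 20 pairs, 25 items,
8 rounds, shortlist 10, two taggers. It emulates the statistical structure
the analysis assumes, with every generating parameter recorded in
`truth.json`.

**Ground model.** Each item has a private vocabulary of `vocab_size = 12`
candidate elements with standard-normal base salience scores `s`. Inclusion
probabilities are `p = clip(λ · softmax(θ_i · s), 0, 1)` with `λ = 4`
expected tags per fresh signal. The concentration `θ_i = θ · exp(ε_i)`,
`ε_i ~ N(0, 0.8²)`, is the predictability knob: high θ piles mass on a few
always-drawn elements (expected pairwise JD → 0), low θ spreads it (JD →
1). The per-item log-jitter gives items a realistic range of `JD_μ` values;
global default `θ = 2`. A fresh ground samples each element independently
with its `p`, resampling until non-empty. The generating "true" `JD_μ` of an
item is the Monte-Carlo mean pairwise JD of fresh samples (400 pairs).

**Signal evolution.** With probability `ρ_reuse = 0.85` a signaller reuses
the previous construal, dropping each tag independently with probability
`δ_drop / (1 + level) = 0.25 / (1 + level)` (at least one kept), where
`level` is the number of consecutive reuses; otherwise they re-construe
from scratch. The level-decaying drop front-loads simplification: signals
converge on a stable conventional core, so chain similarity (and hence the
familiarity rating) rises over turns while ink falls, matching the observed
dynamics of repeated drawing.

**Rendering.** Every tag maps (via a CRC of its label) to 2–4 identical
10×3 bars in disjoint sub-cells of a 32×32 glyph cell; a drawing is the
union of its tags' glyphs on a 128×128 canvas, with simplification level
`s` keeping the first `max(1, m − s)` strokes of each glyph. Identical
disjoint strokes make PC proportional to the stroke count, so ink *and* PC
are non-increasing in the simplification level by construction — the
qualitative property that matters; the drawings make no claim to visual
realism. Complexity is measured on these rendered images.

**Taggers.** Each simulated tagger detects every true element with
probability 0.9 and renames it through a private bijection of the
vocabulary (internal consistency), exercising the content-insensitivity of
`JD_μ`.

**Behaviour model.** Directions encode the phenomena of interest; the
magnitudes are conventions chosen for comfortable statistical power at 20
pairs (the measurements they imitate live on other scales entirely):

- insight: latent `4.0 + 2.5·JD_μ·[first exposure] − 1.0·fam −
  0.5·(time_seen − 1) + N(0, 1)`, rounded and clamped to 1..7. The latent
  continuous scale mirrors treating the 7-point rating as continuous in the
  models while producing integer data. `fam` is the Jaccard similarity to
  the chain predecessor (0 on first exposure).
- accuracy: `Bernoulli(logistic(0.2 − 2.0·JD_μ + 1.0·fam − 0.6·(log PC −
  4.5)))`.
- iconicity rating: `clip(5.5 − 2.0·JD_μ − 0.6·(time_seen − 1) + noise,
  1, 7)` — items with unpredictable grounds draw less iconic signals, and
  iconicity decays as signals simplify.
- familiarity rating: `clip(1 + 6·fam + noise, 1, 7)`, absent on an item's
  first signal.
- rating noise is `σ / √10`, emulating the mean of 10 independent raters
  without simulating them (the mean's distribution is identical, at a tenth
  of the cost).

Randomness is split into independent seeded streams (ground model,
schedules, evolution, taggers, responses), so the whole study — image bytes
included — is bit-reproducible under a fixed seed.

**What passing tests do and do not show.** The generator reproduces the
directional structure (simplification, rising familiarity and accuracy,
falling insight, the `JD_μ`–insight link) with gaussian noise and
independent per-tag sampling. It does not emulate strategic signalling,
receiver inference as a process, inter-item visual confusability, or rater
idiosyncrasies; recovery of the generating signs shows the pipeline is
consistent, not that human data would yield particular magnitudes.

## The model suite

Thirteen analyses, each declared with a maximal random-effects structure
over the crossed factors *item* (cue word) and *participant* (the receiver
for guess responses; the signaller for drawing properties and crowd
ratings):

whole game — log PC ~ turn; accuracy ~ turn; insight ~ turn; insight ~
time + turn; insight ~ time + accuracy + log PC. First exposures — insight
~ JD_μ + iconicity + log PC (no item random effect: one `JD_μ` per item);
insight ~ iconicity; accuracy ~ JD_μ + iconicity + log PC; accuracy ~
iconicity. Older items — iconicity ~ time; familiarity ~ time + time²;
insight ~ time + iconicity + familiarity + log PC; accuracy ~ the same.

Numerical and design choices:

- **Scaling**: `JD_μ`, iconicity, familiarity and log PC are standardised
  (mean 0, sample SD 1) *within each analysis subset* (first-exposure vs
  older rows). `time` enters as the raw count of turns seen; `time²` is
  computed on centred time to limit collinearity.
- **Random effects** use the variance-components parameterisation
  (uncorrelated intercepts and slopes). Gaussian models are fitted by REML
  with statsmodels `MixedLM` (L-BFGS first, Powell warm-started from it if
  the convergence flag is not set — Powell copes better with boundary
  variance components). Binomial-logit models use the package's Laplace
  GLMM (`symsig.mixedglm`): penalised IRLS for the joint mode, Nelder-Mead
  over log random-effect SDs, the standard `log det(Z'WZ·D + I)` Laplace
  correction; it matches plain logistic regression exactly when no random
  effects are declared and agrees with reference GLMM software to well
  within one standard error on test data.
- **Fallback ladder** on non-convergence (non-converged optimiser,
  non-finite or zero fixed-effect standard errors, singular matrices):
  correlations are never modelled (so the conventional first step is built
  in), then random slopes are dropped one at a time in reverse order of
  declaration, then intercepts only; an intercept-only failure is a hard
  error. The structure actually used and every ladder step are recorded in
  the fit.
- **Inference**: p-values are Wald normal approximations, documented as
  approximate and secondary to the parametric bootstrap — simulate
  responses from the fitted model (estimated fixed effects, variance
  components, residual variance), refit with the same structure, and take
  outward-rounded 2.5/97.5 percentile order statistics (so a 2-replicate
  interval is exactly (min, max)). Replicates that fail to converge are
  dropped; if more than 10% fail the CI is flagged unreliable. Bootstrap
  seeds derive deterministically from the suite seed. The default is 200
  replicates; the test suite and the acceptance script use 12–200 depending
  on the check, with the sizes chosen to keep full runs in the minutes
  range.
- Insight (1..7) is modelled as gaussian rather than ordinal — a
  faithful-reproduction choice matching how such ratings are conventionally
  analysed in this literature.

## Known limitations

- The Laplace approximation (binomial) and the Wald p-values are both
  first-order; for small group counts the bootstrap CIs are the inference
  to trust.
- `MixedLM` variance components at the boundary (zero variance) are
  reported as converged fits; the ladder only engages on genuine failures.
- The glyph renderer's PC is exactly proportional to stroke count, which
  is cleaner than scanned drawings; absolute PC values are not comparable
  across renderers or scans, only trends are.
- Real-data mode expects the documented CSV contracts and pre-existing
  familiarity-chain links; it does not re-score human familiarity.
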
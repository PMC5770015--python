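# symsig

Simulation and analysis of **symbolisation** in repeated graphical
signalling games — the drift of drawn signals from iconic sketches to
simple conventional marks as a pair of players interacts, and the shift in
the *inferential* work the receiver does along the way.

In these Pictionary-like games, one player draws a cue item (say, *Harrison
Ford*) and the other guesses, over 8 rounds (4 turns per role) on a 10-item
shortlist from a 25-item pool, with one item replaced every second round to
separate item novelty from game fatigue. The receiver rates each guess for
the strength of the sudden *"Aha!"* (insight) experience on a 1–7 scale.
`symsig` packages the measures and models needed to study when that
insight-style processing is recruited:

- **Perimetric complexity** of a binary drawing,
  `PC = (inside + outside perimeter)² / ink` — a scale-free measure of
  visual complexity (log-transformed for analysis).
- **Ground unpredictability `JD_μ`** — the mean Jaccard distance
  `JD(X, Y) = 1 − |X∩Y| / |X∪Y|` over all pairs of independently produced
  first-exposure signals of an item, after human (or simulated) taggers code
  each drawing's *ground* (the set of salient facts the signaller drew).
  `JD_μ = 0` for code-like items always drawn the same way, `1` when grounds
  never overlap. The measure is content-insensitive (any bijective renaming
  of one tagger's vocabulary changes nothing) and proportional.
- **Familiarity chains** — each signal is linked to the most-resembling
  signal from the previous turn, the comparison against which its
  familiarity is rated, and **time-seen**, the number of distinct turns a
  pair has seen an item.
- A **synthetic-study generator** with known ground-truth parameters: a
  per-item tag-salience model with a single predictability knob θ, a
  signal-evolution model (reuse-and-simplify vs. re-construe), deterministic
  glyph rendering so complexity is measured on real images, two simulated
  taggers, and a behaviour model producing accuracy, insight, iconicity and
  familiarity with the directions of interest built in.
- A **mixed-effects model suite**: thirteen gaussian / binomial-logit models
  with crossed item and participant random effects (variance-components
  parameterisation), a deterministic convergence-fallback ladder, Wald
  statistics, and parametric-bootstrap 95% CIs. Gaussian models are fitted
  with statsmodels `MixedLM`; binomial models use the package's own
  Laplace-approximation logistic GLMM.

## Worked example

```python
from symsig import StudyConfig, simulate_study, run_model_suite, jaccard_distance

jaccard_distance({"MAN", "HAT", "CLIFF", "GUN", "WHIP"},
                 {"MAN", "HAT", "WHIP", "CAR"})   # -> 0.5 (3 of 6 tags shared)

study = simulate_study(StudyConfig(), seed=1)     # 20 pairs, 1600 signals
sig = study.signals
sig.groupby("turn").pc.mean()                     # 156.4, 98.1, 86.5, 78.7
sig.groupby("time_seen").insight.mean()           # 4.21, 2.80, 2.24, 1.78
sig.groupby("turn").accuracy.mean()               # 0.395, 0.570, 0.540, 0.585

suite = run_model_suite(sig, bootstrap_reps=0)
suite["game_insight_time_turn"].coef("time")      # -0.893 (turn drops to +0.080)
suite["new_insight_jd_icon_logpc"].coef("jd_mu_s")  # +0.558
```

Drawings simplify across turns (mean PC 156 → 79), insight ratings fall
with the number of turns an item has been seen (4.21 → 1.78) while the turn
effect vanishes once time-seen is in the model, and the first-exposure
insight rating rises with the item's ground unpredictability (`JD_μ`
coefficient +0.558, bootstrap 95% CI [0.35, 0.77]). Accuracy rises across
turns despite the absence of feedback.

Short narrative scripts, one per capability, live in `examples/`. A thin
CLI wraps the pipeline:

```sh
symsig run --config cfg.yaml --seed 1 --out runs/r1   # generate → measure → model → report
symsig pc --in drawings/ --out complexity.csv
symsig validate runs/r1
```

Runs are fully deterministic under a fixed seed — rerunning a config
reproduces identical file checksums, bootstrap CIs included.

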
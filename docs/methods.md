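# Methods

## The game

The universe `U` is a chart of n color chips with CIELAB coordinates; the
standard layout has 40 hues × 8 lightness values at full saturation plus 10
achromatic chips (n = 330). In each game a target chip `t` is drawn uniformly
from the chart (uniform need probability throughout). The sender observes
`CIELAB(t) + ε_e`, `ε_e ~ N(0, σ_e² I₃)` — *environmental noise*, modeling
real-world color variability of referents — and computes a distribution over
d message slots:

    w = softmax(φ_sᵀ ReLU(θ_sᵀ x + b))          x ∈ R³, w ∈ R^d

The receiver sees a message `m` and reconstructs a distribution over the
chart:

    p(U | m) = softmax(φ_rᵀ ReLU(θ_rᵀ m + b))

A guess `c` is sampled from this distribution and both agents receive the
reward `r = sim(c, t) = exp(-0.001 · dist(c, t)²)`: exact communication pays
1, a near miss pays nearly as much, a distant miss pays essentially nothing.
The kernel scale 0.001 is the standard choice in color-naming analyses; at
CIELAB distance ≈ 26.3 similarity has fallen to ½.

Both networks use k = 20 hidden units and d = 50 message dimensions. d caps
the vocabulary at 50, far above what ever emerges in practice. Weights are
initialized Uniform[-0.1, 0.1] (seed-controlled, configurable), biases zero;
inputs are raw CIELAB coordinates, unstandardized.

## Training variants

**Continuous messages** (the default; faster and used for all sweeps): the
transmitted message is the full probability vector corrupted by *channel
noise*, `m = w + ε_c`, `ε_c ~ N(0, σ_c² I_d)`. The channel is differentiable,
so a single REINFORCE loss trains both agents end to end:

    J(Ω) = -(1/N_b) Σ_n log Π_Ω(c_n | t_n) · r_n

Defaults: batch N_b = 100 games per episode, N = 20000 episodes.

**Discrete messages**: a one-hot word is sampled from the sender softmax and
crosses the channel exactly (channel noise does not apply to a symbol; the
`channel_noise` helper is a documented no-op on discrete messages). No
gradient crosses the channel, so sender and receiver have separate losses,
each using the advantage `r_n - B_n` where `B_n` is the running mean of every
reward observed so far (0 before the first; updated game by game). Defaults:
N_b = 256, N = 25000 — discrete training is noisier and needs both.

Both variants are optimized with ADAM (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8 —
standard defaults, exposed in `GameConfig`). Gradients are derived by hand;
the test suite validates them against central finite differences with the
action draws replayed, which makes the REINFORCE loss a deterministic
differentiable function of the weights. Log-probabilities are floored at
log(1e-12); rows at the floor contribute zero gradient. Rewards are computed
against the clean target chip, not its noise-perturbed coordinates. A
non-finite loss raises `TrainingDivergedError` with the episode index (never
observed under the default configuration).

**Choice of the channel-noise default.** `sigma_c_sq` is a per-component
variance, like `sigma_e_sq`; its default is 0.01, i.e. a noise scale (SD) of
0.1 on a message whose entries live in [0, 1]. This value sits at a
documented sensitivity boundary: at variance 0.1 (SD ≈ 0.32) the receiver's
optimal response to the mostly-noise message dimensions is to null their
input weights, after which no gradient can recruit a new word — the
vocabulary pins at 2–4 terms at *every* environmental-noise level and the
noise–vocabulary trade-off the game is designed to expose disappears. At
scale 0.1 the trade-off is restored (about 5–7 terms at σ_e² = 1 falling to
about 3 at σ_e² = 512, with vocabulary growing during training). The noise
still does its intended job of pushing messages toward peaked, one-hot-like
vectors.

## Extracting a language

After training the sender is queried with ε_e = 0 on every chip and the chip
is assigned the argmax word (`cat(t) = argmax_i w_i(t)`, ties to the smallest
index). The resulting partition is the agent's *mode map*, the analog of a
survey mode map in which each chip gets the term most speakers used for it
(survey ties break to the lexicographically smallest term — deterministic and
seed-free). When evaluation requires messages, discrete one-hot vectors are
used so no extra information leaks through the continuous values.

## Efficiency measures

All costs are in bits under a uniform need probability (the aggregate is the
conditional entropy of the chip given the word under the listener's model).

- **Expected surprise** of a probabilistic naming model p(w|c):
  `-Σ_w p(w|c) log₂ p(c|w)`, with p(c|w) from Bayes' rule under a uniform
  prior. p(w|c) can come from survey respondent fractions or from querying
  the trained sender (softmax at ε_e = 0, no sampling). If a decoder puts
  zero mass on an observed chip the surprise is reported as `inf` with a
  warning — sparse empirical models can produce this; it is never silently
  dropped.
- **KL loss** of a hard partition, via an exemplar-based listener:
  `p(c|w) = Σ_{j∈Cat(c)} sim(c,j) / Σ_{i∈U} Σ_{j∈Cat(c)} sim(i,j)` — the
  chip's similarity mass to the word's category, normalized over the whole
  chart, so each word's reconstruction is a proper distribution. The
  denominator is per-word: a partition-wide denominator would make the cost
  ≈ log₂ n for every partition (Jensen) and erase the random/agent/optimal
  separation this measure exists to show. With a deterministic naming model
  and this same listener, expected surprise and KL loss coincide exactly
  (asserted in the tests). A within-category renormalization variant is
  available behind `per_category_norm`, off by default.
- **Well-formedness**: Σ over within-category pairs of (sim - ½) — the
  maximizing-agreements correlation-clustering objective, reported alongside
  the solver's optimum for scale.
- **Adjusted Rand index** for label-invariant partition comparison, with
  `mean_pairwise_ari` providing group means and 1.96·sd/√n confidence
  halfwidths (a single pair reports CI 0 with `ci_defined=False`).

## Correlation clustering

The solver is greedy best-move local search on the signed graph
(weight = sim - ½, or co-assignment frequency - ½ for consensus maps): sweep
nodes in chip order, move each to the cluster (possibly a fresh singleton)
that most increases the objective, repeat until no move improves; best of 20
seeded restarts (restart 0 starts from all-singletons / round-robin under a
cluster cap). Every accepted move strictly improves the objective, so
termination at a local optimum is guaranteed — but only local optimality is.
On random instances with n ≤ 8 the search finds the exact brute-force optimum
(Bell-number enumeration, n ≤ 12) in ≥ 95% of cases, which is what the tests
pin. Ties prefer the lowest-indexed cluster; `max_clusters` forbids opening
clusters beyond a cap and is used to produce per-k baseline maps.

## Synthetic data

`make_synthetic_chart` emulates the survey chart's geometry: chromatic chips
on an elliptic cylinder in (a*, b*) — hue wraps smoothly, as on the real hue
circle — with L* from the value row, achromatic chips up the L* axis, plus
Gaussian jitter (SD 1) so charts are seed-dependent. Default ranges put the
per-dimension SDs near the real chart's 23.3 / 29.0 / 32.9 (asserted within
±30%). What it does **not** emulate: the irregular spherical form of the real
chart (maximum chroma varies strongly with hue and lightness), its
non-uniform inter-chip spacing, and any perceptual non-uniformity of CIELAB
itself. Results on the synthetic chart therefore show that the *mechanisms*
behave as described, not that trained vocabularies will numerically match
maps derived from the real chart.

`make_planted_language` plants a ground-truth k-way partition — the
correlation clustering of the chart capped at k clusters, with the largest
cluster split by 2-means on coordinates if fewer than k survive — and
simulates speakers who use the planted term except with probability
`confusion_rate` (default 0.1), when they slip to a term of a neighboring
category (categories of the chip's 10 nearest foreign chips). This mimics
boundary disagreement between informants; it does not model speaker-specific
dialects, response sets, or non-adjacent confusions. Defaults: 25 speakers,
matching the average number of survey informants per language.

## Experiment designs and scaling

The full design is σ_e² ∈ {1, 2, 4, …, 512} × 25 replicates × 20000 episodes
(hours of CPU). The package's scaled tier — used by the test suite, the CLI's
`--tier scaled` and the README example — is 3 levels ({1, 64, 512} for the
environmental sweep, {0.01, 0.1, 1} for the channel sweep) × 5 replicates ×
8000 episodes × batch 100, which preserves every qualitative result checked:
negative rank correlation between either noise and vocabulary size, term
growth and KL decline within training (measured after a 500-episode burn-in:
the term count of the first ~10² episodes reflects the argmax pattern of a
still-near-uniform softmax, not a vocabulary), and the efficiency ordering
random ≥ agents ≥ clustering-optimum per term bucket. Replicate seeds derive
from one master seed via `SeedSequence([master, level, replicate])`.

## Known limitations

- The correlation-clustering solver guarantees local optima only; "optimal"
  baselines are best-of-restarts values.
- Continuous-mode vocabularies at desk scale (5–7 terms at low noise) are
  smaller than full-scale runs can reach; absolute term counts are
  scale-dependent even though every trend is not.
- Internal-consistency tables for trained agents are stochastic quantities;
  at scaled replication counts their confidence intervals are wide.
- Two agents only; no populations, no iterated learning, no non-uniform need
  probabilities (the API accepts a prior but all defaults are uniform).
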
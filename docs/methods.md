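# Methods

## The analysis

`gazelm` links a causal language model's next-word predictions to
word-by-word eye-movement behaviour in natural passage reading. Three
per-word quantities are derived by walking each passage with an
incremental moving window (the model sees exactly the words before the
target, never the target itself):

- **Entropy** `H = −Σᵢ pᵢ log₂ pᵢ` of the next-token distribution at the
  target's position, *before* the target is revealed. Low entropy marks a
  constraining context, high entropy a neutral one. Because it is computed
  before the target, any effect of entropy on reading must reflect
  prediction rather than integration of the word itself.
- **Surprisal** `S = −log₂ p(target | context)`, the unexpectedness of the
  word actually encountered, with the target's probability given by the
  chain rule over its subword pieces.
- **Target-prediction similarity**: the cosine between contextual
  embeddings of the model's top predicted word and the actual target, both
  embedded in the same preceding context.

These metrics join a word-level eye-movement report (one row per
participant × word: first-pass skip, first fixation duration, gaze
duration, total reading time, regression-in) and are analysed with
(generalized) linear mixed models with crossed random intercepts:

```
outcome ~ entropy * surprisal + log_frequency + length_letters
          + word_number_in_sentence
          + (1|participant) + (1|word) + (1|text)
```

Binary outcomes (skipping, regressions) use a logistic link and report
odds ratios per bit; duration outcomes are modelled on the natural-log
millisecond scale and back-transformed by exponentiation for
presentation. A prediction-error subset analysis discretizes the
word-level entropy and surprisal into equal-frequency bins, keeps the
low-entropy × high-surprisal cell (confident predictions that were
wrong), and refits the duration/regression models with similarity in
place of the entropy and surprisal terms.

## Language-model backends

Any backend implementing the `LMAdapter` contract plugs in: `tokenize`
(word → subword ids, with a leading-space convention for non-initial
words in byte-pair vocabularies), `logits` (context → next-piece scores),
`piece`/`is_word_initial` (for decoding candidate words), and
`embed_word` (contextual embedding, mean-pooled over the word's pieces).

Two backends ship:

- **`ToyLM`** — an explicit order-k Markov model over a small word
  vocabulary; every word is one piece. Because the conditional table is
  explicit, every pipeline output has a brute-force oracle, which is how
  the test suite checks the walker to 1e-9. Its embeddings are fixed unit
  vectors (cosines exact by construction), not genuinely contextual — a
  deliberate simplification.
- **`TransformerLM`** — a thin adapter over a Hugging Face causal LM
  (reference: the released 117M-parameter GPT-2 base, used as published,
  CPU only). It is an optional extra; nothing in the core package or test
  suite imports it.

Numerical conventions, applied uniformly:

- Internal log-probabilities are natural; all reported quantities are in
  bits (exact division by ln 2).
- Entropy is computed over the next-*piece* distribution at the target's
  first position — that is the model's prediction-probability vector —
  while the target's probability multiplies conditional piece
  probabilities along the whole word (chain rule). The asymmetry is
  intentional: entropy characterizes the pre-target state, surprisal the
  whole word.
- Softmax uses max-subtraction; a subword probability that underflows to
  exactly zero caps the word's surprisal at 64 bits (logged) rather than
  producing infinity.
- Candidate next *words* are decoded from the piece distribution: each of
  the top-m word-initial first pieces (m = max(50, k)) is extended
  greedily with continuation pieces until the next greedy piece would
  start a new word, then candidates are re-ranked by chain probability.
  Ties break toward the lower vocabulary index, so rankings are
  deterministic. Decoding conventions are the main source of slack when
  comparing top-k accuracies across implementations, which is why the
  whole convention is isolated behind `top_k_candidates`.
- Accuracy and cloze scoring normalize word forms identically
  (case-insensitive, punctuation-stripped), so human and model accuracy
  are like-for-like.
- Probability→logit conversion keeps ±∞ sentinels for 0 and 1 (the
  zero-cloze floor is data, not an artefact to clip).
- Equal-frequency binning cuts at empirical quantiles; a value equal to a
  boundary joins the higher bin. Assignments depend only on values, never
  input order. The default is tertiles (configurable 2–5); on real data
  the published size of the low-entropy/high-surprisal subset is the
  empirical calibration target for the bin count.

## Mixed-model estimation

Fitting is delegated to lme4 (`lmer`/`glmer`) through an `Rscript`
subprocess bridge — the standard tool for crossed random-intercept
models — with jobs batched so a simulation study costs one R session.
Choices that matter:

- Maximum likelihood (not REML) for Gaussian models, so fixed-effect
  comparisons across models are coherent.
- Binomial models use the Laplace approximation (`nAGQ=1`); simulation
  studies may use the faster `nAGQ=0` (estimates and standard errors
  agree to ~3 decimals on this package's designs; verified against
  `nAGQ=1`).
- Wald inference throughout: z (binomial) or t (Gaussian) with
  normal-approximation p-values; type-III chi-squares are computed in
  Python as marginal Wald blocks from the coefficient vector and
  covariance matrix (for this all-continuous design each term is its own
  single-df factor, so χ² = z² exactly). `car::Anova(type=3)` output is
  returned by the bridge and used in tests as an independent cross-check.
- Convergence and singular-fit messages from lme4 are propagated to
  `FitResult.converged` / `.singular`; non-convergence is flagged, never
  hidden. Rank-deficient fixed-effect designs raise with the aliased
  term names instead of letting the backend drop columns silently.
- Predictors enter unscaled (bits, log₁₀ per-million, letters, ordinal
  position), so coefficients are per-unit effects. The collinearity
  screen (VIF from regressing each predictor on the others; values below
  2 taken as unproblematic) runs on the main-effect design — the raw
  interaction product is collinear with its mains by construction and is
  not part of the screen.
- The duration scale is checked with a Box–Cox profile-ML λ̂; λ̂ within
  ±0.5 of zero selects the log transform, near 1 the identity. On
  simulated log-normal durations λ̂ lands near 0.

## The synthetic study generator

The generator emulates the *statistical structure* of a passage-reading
eye-tracking study with cloze norms, with every ground-truth parameter
known:

- **Passages**: sampled from the toy model's conditional table; the
  default table is Dirichlet(0.1)-distributed per context, giving a
  realistic spread of constraining-to-neutral contexts (entropies roughly
  2–4 bits over a 60-word vocabulary, mean top-prediction probability
  ≈0.3). Sentence boundaries are inserted every 11 words so the
  word-number covariate varies. Pseudo-words are 2–9 letters so length
  varies; frequencies follow a Zipf-like 10000/rank per million.
- **Cloze norms**: each simulated respondent guesses every non-initial
  word from the model's own conditional distribution; the norm is the
  fraction matching the actual word. Finite pools floor rare words at
  exactly zero — the cloze floor effect that motivates LM-based
  predictability in the first place.
- **Gaze records**: one row per participant × metric-carrying word.
  Skips and regressions are Bernoulli draws from logistic models; log
  first-fixation durations are Gaussian draws; each of the four linear
  predictors uses intercept, entropy, surprisal, entropy × surprisal,
  log frequency, length and word number, plus random intercepts for
  participant, word item and text shared across the four models (one
  draw per grouping level). Skipped words carry absent (NaN) durations,
  never zeros.
- **Duration ordering** (FFD ≤ gaze ≤ total) holds by construction: the
  log-gaze draw shares the FFD residual and adds a non-negative
  refixation increment (probability 0.35, half-normal scale 0.4), and
  total multiplies gaze by a further non-negative re-reading factor.
  Consequence: every slope of the log-gaze model is exactly the
  configured coefficient, while its *marginal intercept* is shifted by
  the increment's mean, `refix_prob · refix_sd · √(2/π)` — exposed as
  `GazeSimConfig.marginal_intercept_shift("gaze")`. Cells where the gaze
  draw would fall below FFD are clamped and counted
  (`attrs["n_gaze_clamped"]`; zero under the defaults).

Default generative coefficients are anchored, where the underlying study
reports an effect, to its sign and per-bit scale — entropy on skipping
ln(0.93) ≈ −0.073/bit, surprisal on regressions ln(1.25) ≈ 0.223/bit,
entropy on regressions ln(1.08) ≈ 0.077/bit, surprisal on log gaze
duration 0.02/bit, and a base skip rate near 45% — with the remaining
values (intercepts ≈ exp(5.35)≈210 ms first fixations, frequency, length
and word-number effects, random-intercept SDs 0.15/0.10/0.05, residual
SD 0.30) chosen once as values typical of reading studies. The
word-number coefficients of both binary models and the interaction terms
of the gaze and regression models are exactly zero, so the simulator
carries genuinely null terms for calibration checks.

What the generator deliberately does **not** emulate: saccade planning,
parafoveal preview, refixation sequences, landing positions, or any
semantic structure in the text (word order carries no meaning; embeddings
are fixed vectors). Passing tests therefore demonstrate that the
*pipeline* — metrics, merging, model fitting, inference — is correct
under the assumed statistical structure; they do not validate the
psycholinguistic claims on real data, which require the real corpus and a
real language model.

## What the tests establish

- Exact identities (1e-9): softmax normalization and shift invariance;
  entropy values and bounds; S = −log₂ p for every emitted state;
  chain-rule additivity over subwords; cosine similarities of constructed
  embedding pairs.
- Oracle equivalence: pipeline H, p, S equal brute-force values from the
  explicit conditional table at every position of sampled passages.
- Structural invariants: prefix invariance of the moving window (metrics
  for word i depend only on words 1..i−1); top-k accuracy monotone in k
  and 1 at k = V; merge conservation (skipped + fixated = total;
  passage-initial words excluded and nothing else); binning permutation
  invariance and the documented tie policy; subset factorization as
  participants × tokens on complete designs.
- Mixed-model contracts: OR = exp(β); χ² = z² for single-df terms;
  agreement of the Python type-III blocks with car::Anova; fits whose
  variance components collapse to the zero boundary equal the
  single-level statsmodels oracle within 1e-4; null-factor p-values
  uniform (KS check over 60 replicates).
- Parameter recovery: 20 seeded replicates at 100 participants × 300
  words (one corpus, fresh gaze draws per seed), fitting all four
  formulas. Each nonzero generative coefficient must be within 2 SE of
  its estimate at a rate statistically compatible with 90% (one-sided
  binomial test per term at the 5% level), and the pooled rate across
  all nonzero terms must reach 90% (observed ≈96%). Generatively null
  terms exceed |z| = 2 at a rate bounded at 15% over 80 pooled trials
  (nominal 5%).

## Problem sizes

Chosen as the package's standard working sizes: the default pipeline
configuration runs a 3-passage × 60-word × 10-participant smoke study
(seconds, including all model fits); `scripts/acceptance.py` runs a
5 × 120 × 50 study with 40 cloze respondents per word (about a minute);
the recovery study uses 100 participants × 300 words × 20 seeds (a few
minutes, with the binary fits at `nAGQ=0`).

## Known limitations

- Toy embeddings are context-free, so the similarity metric's contextual
  character is exercised only by the transformer backend.
- Duration models are fitted on the fixated subset while random effects
  are shared with the skip model; the induced selection is mild at the
  default effect sizes but is a real feature of this design (as it is of
  the real analysis, where skipping is not ignorable either).
- Exact numeric parity with any particular mixed-model software build is
  a non-goal; the contract is tolerance-based agreement plus
  sign/significance agreement.
- The choice of embedding layer for similarity (final hidden layer,
  mean-pooled) and the top-word decoding convention are defensible
  defaults, not uniquely determined; both are isolated behind single
  functions so alternatives are one-line swaps.
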
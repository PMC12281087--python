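# Methods

This note documents the models and procedures implemented in `sentmetrics`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions a user should know about.

## Sentence segmentation and word tokens

Documents are split into sentences at terminal punctuation (`. ! ?` and the
CJK equivalents `。！？`) followed by whitespace or end of text; a trailing
unterminated span forms a final sentence. Words are whitespace tokens with
leading/trailing punctuation and symbol characters stripped; tokens that are
pure punctuation vanish. This is the simplest reproducible convention —
there is no universally agreed definition of "word", and scripts without
spaces (Chinese, Japanese) must arrive pre-tokenized, which the corpus
reader dialect declares. Whether punctuation tokens should count as words is
a convention, not a fact; excluding them keeps `mean_word_length` a property
of lexical material only.

Control predictors per sentence:

- `mean_word_length`: arithmetic mean of character counts of the words.
- `mean_log_wordfreq`: mean natural-log *relative* frequency (count divided
  by the frequency table's declared total). Natural log is used wherever
  "log" is unqualified in this package. Out-of-vocabulary words receive a
  Laplace floor count of 1 by default (keeping the log finite); `skip` and
  `error` policies are available.

Reading speed is `word_count / total_fixation_duration` in words per second
(durations are read in milliseconds and converted). The log transform is
applied only at the evaluation stage, not at computation time, so the stored
tables remain in interpretable units.

## Backends

All metrics consume a `ScoringBackend`: token conditional probabilities,
a next-sentence probability, sentence embeddings, each gated by capability
flags. Probabilities must lie in (0, 1]; no NaN/Inf ever escapes the
contract. The bundled backends are deterministic and exactly analysable:

- **uniform**: p = 1/|V| for every token — surprisal depends only on length.
- **bigram**: add-α smoothed first-order Markov model (α = 0.5 by default;
  α = 0 gives unsmoothed maximum-likelihood conditionals and raises on
  unseen pairs). Distributions provably sum to 1 and are enumerable, which
  makes brute-force oracle checks exact.
- **certainty stub**: p = 1 always; zero surprisal by construction.
- **bag-of-words embedder**: term-frequency vectors over a fixed vocabulary
  ordering plus one out-of-vocabulary dimension, so no non-empty sentence
  embeds to the zero vector and cosines are always defined.
- **Jaccard NSP**: p = ε + (1 − ε)·Jaccard(word bags) with ε = 0.01 —
  monotone in topical overlap and bounded away from 0 so NSP surprisal stays
  finite. An absent previous sentence counts as an empty bag.

Adapters for real (multilingual) LLMs are a contract, not a shipped
implementation: a causal model maps directly onto token scoring; a masked
bidirectional model asked for causal scoring should mask all right-context
positions, and may score NLL as a pseudo-log-likelihood with full remaining
context. Embedding pooling for such adapters is mean pooling over final-layer
token vectors. Nothing downstream depends on more than the contract.

## Surprisal estimators

For target sentence tokens t_1..t_n and context C (default: the 3
immediately preceding sentences; fewer near the document start; no padding):

- `CR = −Σ_k ln p(t_k | C ⊕ t_1..t_{k−1})` — the joint −ln p(s | C).
- `NLL = CR / n` on causal backends; the per-token normalization removes the
  length dependence, and on bidirectional backends the per-token scores may
  come from masked scoring instead. Whether to normalize is configurable;
  normalized is the default and the distinction from CR documented here is a
  package decision.
- `NSP = −ln p_next(prev, s)`, inherently a two-sentence window (the config
  forces `context_sentences = 1`); the document-initial sentence is scored
  against an empty previous sentence.

Context is truncated at the token level (oldest first) when it exceeds the
backend's token limit. Values are in nats by default, bits on request. All
values are ≥ 0 and finite; `n_tokens` counts the backend's own tokens (for
the toy backends these coincide with words).

Useful identities, all tested: CR is additive over sentence concatenation;
NLL·n = CR exactly on causal backends; a uniform backend gives n·ln|V|.

## Memory-aware sentence relevance

For target t with preceding neighbours c1 = t−1, c2 = t−2 and following
neighbour n1 = t+1:

```
relevance(t) = w_c1·cos(e_t, e_c1) + w_c2·cos(e_t, e_c2) + w_n1·cos(e_t, e_n1)
```

Default weights {c1: 1.0, c2: 0.5, n1: 0.3}. The recency-decay reading —
the immediately preceding sentence carries the largest weight — matches the
cognitive motivation (working-memory recency; contextual influence decays
with distance). The source formulations of this weighting are not fully
consistent with one another, so the assignment is configurable and a preset
with the largest weight on the two-back sentence (`eq1-literal`) is
provided. The target's self-similarity is excluded. At document boundaries
absent neighbours contribute nothing and weights are *not* renormalized;
this keeps two exact properties: relevance is linear in the weights, and
|relevance| ≤ the sum of the present neighbours' weights. A single-sentence
document scores 0 (empty sum).

## Synthetic reading data

The generator emulates the *shape* of a multilingual eye-tracking reading
corpus: `n_languages` languages (default 3), each with its own battery of
documents (default 10 × 12 sentences — 120 sentences per language) read by
`n_participants_per_language` participants (default 20), giving 7,200
sentence-reading records by default — sized for minutes-scale test runs,
roughly two orders of magnitude below a full multilingual corpus. Content is
synthetic: words are drawn from a Zipfian pseudo-word vocabulary (500 types,
exponent 1.1; word lengths 1 + Poisson(3)); sentence lengths are
Poisson(mean 12) with a floor of 3. The frequency table holds the
*generating* Zipf counts (normalizer 10⁶), mirroring how corpus-external
frequency norms relate to any particular text.

Metrics for the generative model come from the toy backends run on the
generated corpus itself: surprisal from a corpus-fitted bigram model,
relevance from bag-of-words embeddings. The generator's surprisal default is
**NLL** (per-token): raw CR grows linearly with sentence length (sd ≈ 16
nats here), so a fixed coefficient on CR would swamp every other effect and
make the response essentially deterministic; the per-token variant keeps all
effects on comparable, realistic scales.

Reading records follow a log-linear model with known coefficients:

```
ln(speed) = b0 + b_len·leñ + b_freq·freq̃ + b_surp·surp̃ + b_rel·rel̃
            + language_offset + participant_intercept + ε
```

where x̃ denotes the predictor centered at its corpus mean (so b0 is the
average sentence's log speed, and differences on a predictor translate
exactly into exp(β·Δ) speed ratios), `participant_intercept ~ N(0, σ_p²)`,
`language_offset ~ N(0, σ_lang²)` drawn once per run, `ε ~ N(0, σ_e²)`.
Defaults: b0 = ln 2 (≈ 2 words/s), b_len = −0.05, b_freq = +0.05,
b_surp = −0.1, b_rel = +0.1, σ_p = 0.1, σ_lang = 0.05, σ_e = 0.2. The truth
is deliberately *linear* in each predictor: a linear truth is the simplest
structure a penalized smooth must recover, making effect signs and
magnitudes — not curvature — the recovery surface. Durations are
back-computed as `word_count / speed`, and the per-record linear-predictor
decomposition is returned as ground truth.

What the generator does **not** emulate: fixation-level microstructure
(saccades, skips, regressions), non-linear true effects, cross-language
typological differences, or the marginal distributions of any real corpus.
Passing tests therefore demonstrate that the estimators and the evaluation
machinery are correct and well calibrated — not that the effects exist in
human data.

A separate helper draws surprisal and relevance columns *independently*
(lognormal and Gaussian), used to verify that the correlation machinery
reports ≈ 0 when metrics genuinely share nothing.

## Evaluation

`build_sentence_table` inner-joins reading records with metric tables on
(doc_id, sentence_index), attaches the control predictors, and sets the
response to ln(words/second); unmatched rows are counted and logged, an
empty join is an error, and non-finite values are rejected.

Model fitting is delegated to mgcv through `Rscript` (data as TSV, specs and
results as JSON): penalized thin-plate-spline smooths with basis size k = 9
per term, smoothing parameters by REML, language as a parametric factor,
participant as a random intercept (`bs="re"`). Random slopes are out of
scope. The per-language (`by = language`) smooth variant is expressible
through `SmoothTerm(by=...)` but is not part of the required surface. The
reported AIC is the conditional AIC of the fitted penalized-likelihood
object (mgcv's corrected definition), and ΔAIC = AIC(full) − AIC(base) is
computed from fits run in the *same* engine session on identical rows —
models fitted on different rows refuse to compare. Significance of a smooth
uses the approximate F-test p-value with a raw p < .01 convention; no
multiple-testing correction is applied.

Partial effects are exported on a 100-point grid over each smooth
predictor's observed range with other covariates pinned (numeric → median,
factors → first level), centered as mgcv centers them, with pointwise 99%
confidence bands. The "slope" of a smooth, used for sign and magnitude
recovery, is the least-squares line through the gridded curve; under the
linear generative truth it estimates the coefficient, with a sampling SE of
roughly 9% of the default β at the default problem size — hence magnitude
recovery is asserted on the mean over replicates, while sign recovery is
asserted per replicate.

Metric correlations use Spearman's rank correlation with average-rank tie
handling (scipy); constant inputs are an error, not a 0.

## Reproducibility and numerical notes

- Every source of randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; a fixed seed yields byte-identical
  corpora, metric tables, and reading tables across runs.
- mgcv REML fits are deterministic given identical data, so model outputs
  are reproducible to the digit.
- Table writers emit floats in Python's shortest round-trip representation;
  reader/writer pairs are exact inverses on valid tables.
- Cosines are clipped to [−1, 1] against floating-point drift; zero vectors
  are an error (the bag-of-words OOV dimension prevents them arising from
  real sentences).
- Degenerate inputs fail loudly: empty documents, empty frequency tables,
  non-positive durations, constant predictors, rank-deficient or
  non-converged fits all raise diagnostic errors rather than returning
  silent values.

## Known limitations

- No shipped adapter for real transformer LMs; conclusions from the toy
  backends transfer to the metric definitions, not to any particular LLM's
  probability estimates.
- The NSP surrogate is a lexical-overlap heuristic; it shares only the
  interface and boundedness of a trained NSP head.
- The evaluation stage requires an R installation with mgcv at run time.
- Smooth-term p-values in additive models are approximate; they are used
  with the fixed p < .01 convention, not as calibrated error rates.
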
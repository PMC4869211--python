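# Methods

This note documents the models and procedures implemented in `pharmwatch`,
the assumptions behind them, the synthetic data they are exercised on, and
the numerical choices made where the design was genuinely open.

## Problem setting

The target quantity is the *signal*: tweets in which a person reports their
own experience with HIV antiretroviral treatment. In a keyword-matched
stream these are extremely rare (well under 1%), buried in news/link posts,
retail spam, tweets matching the drug abbreviation FTC in its Federal Trade
Commission sense, and foreign-language text. The pipeline is a sequence of
increasingly specific filters, each cheap stage reducing volume so the
expensive stages (feature classification, human-style annotation) operate on
a manageable, signal-enriched sample.

## Tokenization and keyword matching

Tokens are maximal runs of word characters with internal dots, hyphens and
apostrophes preserved, case-folded. This keeps URL shorteners (`t.co`,
`bit.ly`) and hyphenated terms (`anti-hiv`) as single tokens while hashtag
and mention markers fall away. Keyword matching is by whole token — never
substring — so compound words (e.g. *giftcard*) do not trigger the keyword
FTC; multi-word keywords ("HIV treatment") match as consecutive token
sequences. Matching is case-insensitive throughout: tweets mix case freely
and the sources give no reason to distinguish it.

## The exclusion cascade and its Poisson audit

Three stages of union-of-rules exclusion filters (link tokens / HIV-prefixed
text; `http`, `news`, `buy`; a larger retail-and-foreign token list) are
applied in order. Within a stage rules are unioned, so rule order is
irrelevant and stages are idempotent — both properties are tested against an
independent set-algebra oracle.

Each filter is justified by a sampling audit. Labeling a reference sample of
n tweets and finding k signal, the expected signal in an audit sample of
size m is the Poisson-scaled

    lambda = k * m / n,    sigma = sqrt(lambda).

If each of r independent audit samples of rule-*matching* tweets contains
zero signal, the probability of that outcome — hence a bound on the chance
the rule discards appreciable signal — is

    P(loss evidence) = exp(-r * lambda).

This plug-in formula is documented explicitly because it is the package's
definition: no integration over the rate uncertainty is performed (at the
lambdas involved it would change nothing material). Audit samples are drawn
without replacement; at stream scale the finite-population correction is
negligible and omitted. Comparing signal proportions between rule-matching
and non-matching samples uses the exact conditional binomial test (given
k1+k2, k1 ~ Binomial(k1+k2, n1/(n1+n2))), two-sided at alpha = 0.05.

## English detection

A tweet's English score is the fraction of its tokens belonging to a
closed-class English function-word list (~170 words including the clitic
fragments apostrophe-free tweet spelling produces: "i m", "it s"). Tweets
scoring below 0.15 are removed. The threshold was chosen so that realistic
first-person English tweets — which are short but pronoun- and
preposition-dense — score well above it, while token salads from foreign
dictionaries score near zero. This is a deliberately simple detector; it is
not a general language identifier and would misjudge, e.g., English noun
phrases with no function words.

## The nine features

* `personalcount` — occurrences of first/second-person pronouns
  {i, me, my, mine, we, us, our, you, your}.
* `tagnoun` — heuristic open-class noun count: tokens that are not function
  words or pronouns, not numeric, and not carrying `-ly`/`-ing`/`-ed`
  inflection. A statistical POS tagger would be more accurate; the heuristic
  is deterministic, dependency-free, and retains the separation power the
  classifier needs (objective news text is noun-dense, personal reports are
  pronoun-dense).
* `sis_signal`, `sis_noise` — the tweet's average per-token log-probability
  under additive-smoothed unigram models fitted to the signal and noise
  training corpora (pseudo-count 0.5, one unseen bucket). Length
  normalization stops tweet length from leaking into these features, which
  `ncharacters` already carries.
* `bigrams_noise` — the analogous average log-probability over consecutive
  token pairs under the noise bigram model.
* `is_english` — the function-word fraction described above.
* `common_signal`, `common_noise` — number of tweet tokens in the top-K
  (default 50) most frequent tokens of each training class, after removing
  tokens present in both top-K lists (shared tokens carry no separation
  power). Frequency ties break alphabetically for determinism.
* `ncharacters` — raw character length.

Token-free tweets take the unseen-token smoothing floor for the likelihood
features and zero counts elsewhere. Feature extraction is pure: identical
tweet and models always give the identical vector.

## Classifier and threshold calibration

One classifier family is used at a time, configurable between a
margin-based model (logistic regression on standardized features, balanced
class weights — the default) and a tree ensemble (gradient boosting). The
score is the model's signal-class probability in [0, 1]. The ROC sweep in
`evaluate` lets users compare families; no automated hyperparameter search
is performed beyond the defaults.

The working threshold is *not* chosen to maximize accuracy. It is calibrated
on held-out signal to guarantee a target signal efficiency (default 90%):
tau is the k-th largest held-out signal score with k = ceil(target * n) —
the largest threshold keeping at least the target fraction, ties resolved
toward larger tau (maximal noise rejection at the guaranteed efficiency).
This matches exhaustive enumeration on all score sets tested. Consensus
signal is split 60/40 (train/calibration, seeded) so the calibration scores
are not the training scores.

When training annotations contain a single class no classifier can be fit;
the pipeline then passes cascade survivors through unchanged and flags the
report, rather than failing — single-class corpora are legitimate inputs in
testing.

## Consensus annotation and sentiment

Each sampled tweet is rated by exactly two raters on four categories:
(1) personal medication experience, (2) medication but not personal,
(3) irrelevant, (4) not English. Only concordant tweets are kept; category 1
is signal, 2–3 noise, and 4 a non-English control set. With independent
raters at error rate e (symmetric-uniform over wrong categories), expected
agreement is (1−e)² + e²/3 — at e = 0.12 about 78%, the regime observed with
human crowd workers.

Sentiment is an integer in [−5, 5]. Psi over a window is the plain mean;
each rating carries a unit systematic uncertainty, giving sigma(Psi) =
1/sqrt(N) — deliberately *not* the sample standard error, since the dominant
uncertainty is the rating scale itself, not sampling noise. Tweets without a
rating are excluded, never imputed as 0. Time bins are half-open
[origin + i·W, origin + (i+1)·W) with W = 60 days; a boundary timestamp
belongs to the later bin; the bin origin defaults to the corpus start date.
Polarity is strict-sign: negative < 0 < positive, 0 neutral.

Side effects are tabulated as unique-user (drug, effect) pairs — a user
repeating the same report is counted once — with retweets ("RT @" prefix)
excluded, plus the fraction of contributing tweets tagged as reporting good
tolerance ("no side effects").

## Community network

The community graph is the directed follow graph induced on users who posted
signal tweets, keeping each node's platform-wide follower count as an
attribute. "Subgraphs of connected components" are computed on the
undirected projection — the natural reading when tie *existence* rather than
direction is at issue — and both directed and undirected edge counts are
reported so either convention can be checked. Reciprocity is the per-node
count of mutual follows; within-community follower counts are in-degrees in
the induced graph. Percentages in demographic summaries are rounded
half-up to one decimal, matching tabular reporting conventions.

## The synthetic corpus

The generator emulates the statistical structure of the real stream, not its
language. Defaults (the study conditions):

* 100,000 tweets, 1% signal, 5% foreign, timestamps uniform over
  2010-09-09 → 2013-08-28. The real stream's signal rate is ~0.004%; at that
  rate a testable corpus would need millions of tweets, so the desk-scale
  default raises it to 1% while preserving extreme class imbalance.
* Noise: 85% carries cascade-target tokens (links, news, retail, FTC
  commerce, HIV-prefixed announcements) drawn verbatim from the exclusion
  lists, so filter tests are aligned by construction; the remainder is
  third-person drug talk (70%) and off-topic filler.
* Signal: sentiment-keyed first-person templates that always name a drug
  (Atripla and Truvada weighted heaviest), name a side effect when negative,
  and occasionally report good tolerance when positive (13%, putting the
  well-tolerated share of effect-relevant tweets near the observed ~8%).
  Sentiment is drawn from a neutral-heavy, slightly negative distribution
  (mean −0.175), matching the observed predominance of neutral ratings with
  negative outnumbering positive. Truvada tweets in mid-2012 occasionally
  carry prevention/approval wording, reproducing the PrEP-approval mention
  spike for the event-substring series.
* Users: 2,000 profiles, 256 in the signal community; platform follower
  counts lognormal with mean ~2,300; community gender mix 48/16/36
  male/female/unidentified. Follow edges: each community pair connects with
  probability 0.01 and is mutual with probability 0.5; background pairs are
  10× sparser — giving a sparse, fragmented community graph with strong
  reciprocity.
* Simulated raters: symmetric-uniform category errors, optional ±1 integer
  sentiment perturbation (clipped). The drifting-sentiment helper generates
  rounded clipped normal ratings around a linearly drifting mean for
  bin-tracking tests.

What the generator does **not** emulate: real lexical diversity, sarcasm and
figurative language, user-level longitudinal behavior, bursty posting, or
adversarial spam. Passing tests therefore demonstrate the pipeline's
statistical machinery — filter algebra, audit arithmetic, calibration
guarantees, uncertainty propagation, network measures — under controlled
conditions; they do not certify classifier accuracy on real tweets, where
feature separation is far weaker than between templated classes.

## Numerical and design choices

* All randomness fans out from a single seed via independent spawned
  generator streams; same config + seed gives byte-identical outputs.
* Malformed corpus lines fail loudly with line numbers; `skip_bad_lines`
  opts into counted skipping.
* The FTC discard removes tweets whose *only* keyword match is FTC; tweets
  also matching a drug name are kept. The alternative (dropping every
  FTC-matching tweet) would silently lose genuine emtricitabine mentions.
* Empty rating sets make Psi raise, not return a default; empty interior
  time bins are emitted with n = 0 and no Psi.
* The exact binomial comparison and the exp(−r·lambda) loss bound are
  single-rule decisions; no multiplicity control is applied across audited
  rules.
* Reported problem sizes in the reference study (100,000 tweets; 10,000 for
  cascade oracles; 4,000 for rater agreement) were chosen as the smallest
  scales at which the binomial/Poisson property bands are sharp.

## Known limitations

* The noun counter and English scorer are heuristics; on real multilingual
  streams a POS tagger and a trained language identifier would be drop-in
  improvements behind the same feature names.
* The loss-probability bound uses the plug-in lambda and assumes audit
  samples are independent; overlapping samples would weaken it.
* Threshold calibration guarantees efficiency on the calibration sample
  only; generalization efficiency fluctuates by the usual binomial error,
  which the end-to-end retention band accounts for.
* The generator's class-conditional templates make classes nearly separable;
  real operating points at 90% signal efficiency reject far less noise than
  the synthetic study suggests.
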
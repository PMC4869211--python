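# pharmwatch

Social-media pharmacovigilance: extracting the rare first-person reports of
personal drug-treatment experience — here, HIV antiretroviral therapy — from
a large, overwhelmingly noisy keyword-matched tweet stream, and summarizing
what those reports say about drug tolerability, sentiment, and the community
posting them.

The package is aimed at digital-epidemiology and pharmacovigilance
researchers who need the full chain — stream filtering, statistical audit of
every filter, feature-based classification at a controlled signal
efficiency, consensus human annotation, and downstream time-series/network
summaries — as tested, reusable code. Because commercial tweet streams
cannot be redistributed, a synthetic-corpus generator with complete ground
truth stands in for the data, making every stage verifiable end to end.

## The method

A stream of tweets matching antiretroviral brand names (Atripla, Truvada,
Sustiva, ...) plus a few treatment phrases is dominated by *noise*: news and
link posts, retail spam, commerce tweets matching the drug abbreviation FTC,
and foreign-language text. The *signal* — first-person reports of personal
treatment experience — is well below 1% of the stream. The pipeline:

1. **Token keyword matching.** Tweets are tokenized (case-folded; URL
   internals like `t.co` and hyphenated terms like `anti-HIV` survive as
   tokens) and kept if a keyword matches as a whole token, which already
   removes compound-word false matches such as *giftcard* → FTC. Tweets
   whose only match is FTC are discarded.

2. **Audited exclusion cascade.** Three consecutive stages remove tweets
   containing link tokens (`t.co`, `bit.ly`) or starting with "HIV"; tweets
   containing `http`, `news`, or `buy`; and tweets containing a larger set of
   retail/foreign tokens. Each stage is justified by a sampling audit: hand
   labeling a random sample of *n* rule-matching tweets, scaling the signal
   count *k* observed in a reference sample under a Poisson model,

   λ = k·m/n,  σ = √λ,

   and bounding the probability of losing signal when every one of *r*
   matching audit samples contains zero signal by exp(−r·λ).

3. **Nine-feature classification at fixed signal efficiency.** Each
   surviving tweet becomes a nine-feature vector (pronoun count, noun count,
   class-conditional unigram/bigram log-likelihoods, English function-word
   fraction, class top-K token counts, character length) scored in [0, 1] by
   a supervised classifier trained on consensus-annotated samples. The
   working threshold τ is the largest score retaining a target fraction
   (default 90%) of held-out true signal; the classifier is judged by its
   noise rejection at that fixed signal efficiency.

4. **Consensus annotation and summaries.** Two independent raters categorize
   sampled tweets; only concordant labels are kept. Sentiment is an integer
   in [−5, 5]; the sentiment statistic over a time window is

   Ψ = mean of ratings,  σ(Ψ) = 1/√N,

   from a unit systematic uncertainty per rating. Drug mentions and event
   substrings (`prep`, `prevent`, `prophy`, `approv`) are binned in 60-day
   windows, side effects are tabulated per drug over unique users
   (retweets excluded), and the follower network of the identified community
   is summarized by within-community degree, reciprocity, and connected
   components of the undirected projection.

## Worked example

Run the reference synthetic study — a 20,000-tweet stream with 1% signal —
from the shell:

```text
$ pharmwatch study --n-tweets 20000 --seed 7
          ingested: 20000
   keyword-matched: 16685
       ftc-dropped: 14202
links-and-hiv-prefix: 8293
     http-news-buy: 2562
retail-foreign-tokens: 2095
           english: 2095
        classified: 184
signal retention 87.2%, noise rejection 100.0% (ground truth)
Psi = -0.071 +- 0.074
polarity: 44 negative, 109 neutral, 31 positive
community: 317 undirected edges, 30 components, mean follower count 2175
```

Reading the output: the cascade shrinks the stream from 20,000 to 2,095
candidates; the classifier (threshold calibrated at 90% signal efficiency)
keeps 184 tweets, which against ground truth recovers 87.2% of all true
signal while rejecting essentially all noise. The recovered reports carry a
slightly negative average sentiment (Ψ = −0.07 ± 0.07), and the posting
community's follow graph is sparse and fragmented (30 components) with a
heavy-tailed platform follower count averaging ~2,200.

The filter-audit arithmetic is available directly:

```text
$ pharmwatch audit --observed 24 --sample-size 500 --target-size 140 --zero-replicates 3
{
  "expected": 6.72,
  "uncertainty": 2.59,
  "loss_probability": 1.76e-09,
  "decision": "discard_rule_targets"
}
```

i.e. 24 signal tweets among 500 imply 6.7 ± 2.6 expected in a 140-tweet
sample; finding zero in three such samples makes signal loss from applying
the rule vanishingly unlikely.

Other subcommands: `simulate` (write a labeled synthetic corpus),
`filter`, `sentiment`, `community`, `trends`, and `run` (file-level
end-to-end pipeline). Every stage is also importable from `pharmwatch`.

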
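# Methods

This note documents the models, the synthetic data they are validated
against, the numerical choices, and the known limitations of the package.

## Analysis periods and ingestion

The analysis compares two contiguous calendar windows around an event
boundary.  The default study conditions are a pre period of 2020-01-01 to
2022-05-01 and a post period of 2022-05-02 to 2022-10-17; the boundary date
is inclusive on the pre side.  Day binning uses the UTC calendar date of
the timestamp.

Deduplication keys on whitespace-collapsed, lowercased text; record ids are
ignored, so verbatim reposts with fresh ids collapse to their first
occurrence.  Tokenization is deliberately simple and fully specified:
lowercase; URLs removed; @-mentions replaced by a placeholder token;
hashtag signs stripped with the tag word kept; splits on anything outside
[a-z0-9].  The base tokenizer keeps every nonempty token — embedding
training wants complete context windows — while the LDA/TF-IDF
preprocessing additionally drops stop words and tokens shorter than two
characters (with "ob" and "phi" whitelisted, since they are analysis terms
of interest).  No language detector is applied: non-English content is
expected to concentrate into its own LDA topics and be excluded by topic
selection.

## Topic model

LDA is fitted by collapsed Gibbs sampling with symmetric priors.  Defaults:
K = 20 topics, β = 0.01, 1,000 iterations with 200 burn-in, and the
document-topic/topic-word distributions estimated from post-burn-in
averaged counts with Dirichlet smoothing.  The sweep visits documents and
tokens in fixed order with one seeded RNG, so fits are bit-reproducible;
the inner loop is numba-compiled.

The document-topic prior α matters for the membership filter.  The
classical heuristic α = 50/K (the configured default when α is unset) suits
long documents; tweets of ~10 informative tokens can never reach 0.95
posterior mass on one topic under it, because the posterior row is
(n_dk + α)/(n_d + Kα).  Pipeline configurations for tweet-length documents
therefore set α = 0.1, which lets a document dominated by one topic's
vocabulary concentrate ≥ 0.99 of its mass there.  Topic selection is an
operator input: either an explicit index list or the `salient_topics`
helper, which ranks topics by how many designated salient terms appear in
their top terms — mirroring how an analyst reads topic term lists, while
keeping the choice explicit and logged.  Membership for filtering sums the
posterior over all selected topics; training documents are scored with the
stored training mixtures, held-out documents by Gibbs fold-in with the
topic-word distribution fixed.

## Sentiment

The classifier is a plug-in contract: any callable mapping text to three
probabilities (negative, neutral, positive).  The production model used on
real data (a fine-tuned transformer) is external trained weights and is out
of scope; the shipped default is a marker-lexicon classifier that is exact
on synthetic corpora by construction.  Labels encode as 0 / 0.5 / 1.0 and
are averaged per day.  Argmax ties break toward neutral, then negative —
conservative, keeping the encoded mean centred.  Missing days are filled
with 0 for engagement (no posts means no users) and by linear interpolation
for sentiment (the mean of an empty day is undefined, and the
counterfactual model needs a regular grid).

## Counterfactual model

The pre-period series is a Bayesian local level — a random-walk latent
level plus observation noise — with no regression component: no control
series exists for a platform-wide event, so the counterfactual must come
from the pre-period dynamics alone.  Seasonality is likewise omitted; at
the horizons analysed the random walk dominates, and this is recorded as an
assumption rather than a finding.

Sampling alternates a forward-filter backward-sampling draw of the level
path with conjugate inverse-gamma draws of both variances, priors
IG(0.01, 0.01).  The initial level prior is N(y_1, 10·Var(y)).  Defaults:
4 chains × 2,500 iterations, 500 burn-in each (8,000 retained draws);
split-R̂ on both log-variances is reported.  A constant series is a
degenerate fit: a warning is logged and variances are floored at
1e-9·max(Var(y), 1).  Note the weakly-informative prior leaves a small
residual variance (≈ b₀/(n/2)) even on noise-free data, so the
"counterfactual equals the constant" degeneracy holds to a fraction of a
percent, not machine precision.

Engagement counts are modelled on log(1+y) and back-transformed per draw
(count heteroscedasticity); sentiment means stay on the raw [0, 1] scale.
Per draw, the absolute effect is the post-period mean of
(observed − counterfactual) and the relative effect is the percentage
change of totals; intervals are central posterior quantiles.  The tail-area
probability is (1 + #draws on the no-effect side of zero)/(1 + #draws),
one-sided in the direction of the median effect; the add-one term keeps it
strictly positive.  For count series, draws with nonpositive
back-transformed totals are rejected with a logged count.

Because the direction is chosen by the data, this p behaves like a
two-sided test at twice the nominal level under the null: with a calibrated
posterior, p < 0.05 occurs in ≈ 10% of null replications, not 5%.  The
implementation was verified against the exact joint-Gaussian predictive at
the true variances (identical coverage), so this is a property of the
statistic, not a sampler artefact; users wanting a strict 5% false-positive
rate should fix the direction a priori or halve the threshold.

## Trust dimension

One SGNS model is trained per period (the alternative — one joint model —
would conflate the periods; within-model projection also avoids any
cross-model alignment step such as Procrustes).  Training is plain SGD on
the skip-gram negative-sampling objective with a linearly decaying learning
rate, dynamic window, unigram^0.75 negative sampling, and frequent-word
subsampling; single-threaded and deterministic given the seed.  Defaults:
d = 100, window 5, 5 negatives, 5 epochs, min count 5, subsample 1e-3.
Target vectors are the input (centre-word) matrix.

The axis is built from paired antonym anchors; each in-vocabulary pair
contributes the unit-normalised difference of its vectors and the axis is
the unit-normalised mean, so no single anchor pair dominates.  Pairs with
an out-of-vocabulary member are skipped and logged.  A term's score is the
cosine of its vector with the axis; out-of-vocabulary terms carry a marker,
never a default score, and pre/post deltas are reported only when both
periods score.

Projection scores carry no analytic uncertainty; the planted-recovery tests
treat the *sign* across seeds as the stable quantity, which is the level at
which synthetic recovery is asserted.

## Term volumes

TF-IDF uses tf = raw in-document count and idf = ln(N/df), unsmoothed, so a
term present in every document weighs zero and small cases are exactly
checkable by hand.  "Negative or positive sentiment" means the argmax
label; neutral tweets belong to neither panel.  Counts per (term, period,
polarity) use token-set membership, and z-scores are computed within each
polarity panel (population standard deviation; an all-equal panel maps to
zeros).  The exemplar threshold is a per-term weight quantile (default
0.95) with ties at the cut kept — a rank cut and a fixed weight were the
alternatives; the quantile keeps the selection size roughly stable across
terms of very different frequency.  Tweets containing URLs are excluded
from exemplars as a cheap proxy for headline/link posts.

## Synthetic corpora and what passing tests show

The generator plants, per tweet: a topic (from per-period mixtures over
word lists, including a celebrity-confounder topic), a sentiment label
(realised as one token from three disjoint marker lexicons), optional
background anchor "moods" (same-pole anchor words co-occurring, which gives
the trust axis its geometry), optional trust-plant insertions (a target
term plus Poisson-many anchors of the directed pole within a small window),
and short connective fillers that make texts collision-free so a duplicate
rate of zero really means zero duplicates.  Daily unique users are Poisson
with a multiplicative post-period step; each active user posts
1 + Poisson(tweets_per_user − 1) tweets.  One RNG stream, seeded once,
drives everything in fixed order.

Default conditions mirror the real study: the 2020-01-01/2022-05-01/
2022-10-17 windows, an engagement step of ×6.77 (a +577% relative effect),
and sentiment mixes with encoded means 0.44 pre and 0.35 post.  The demo
and test corpora are scaled down (tens of days, ~10-25 users/day) so the
full pipeline runs in minutes on one CPU; the replicated impact simulations
use n_pre = 300, n_post = 150 with σ_level/σ_obs = 0.2 at level ≈ 100,
emulating the slow-drift, noise-dominated character of daily series.

Synthetic text has none of the statistical texture of natural language — no
Zipfian tail, syntax, polysemy, or topic drift — and the lexicon classifier
is exact only because the generator makes it so.  Passing tests therefore
demonstrate that the *analysis machinery* recovers planted engagement
steps, sentiment shifts, topic partitions, and co-occurrence polarities at
realistic sizes and noise levels; they say nothing about classifier
accuracy or embedding quality on real tweets.

## Known limitations

- The local level cannot separate a gradual pre-existing trend from the
  event's effect; a drifting pre period will partly absorb into the
  counterfactual.
- LDA topic indices are seed-dependent; topic selection is by content
  (term lists), never by index constancy across fits.
- SGNS scores on small corpora are noisy in magnitude; only signs and
  orderings are treated as meaningful.
- Deduplication is exact-text only; near-duplicates (added hashtags,
  truncation) survive.
- The per-day unique-user definition counts a user once per day, not once
  per period; the two differ when users are active on many days.
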
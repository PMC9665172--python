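# Methods

## The problem

Public-health emergencies such as the Wuhan lockdown of 23 January 2020
produce population-scale emotional responses that are visible in social
media. `emotraj` implements a complete, reproducible version of the
standard analysis chain for such data: dictionary-based affect scoring of
short microblog posts on the circumplex plane (valence x arousal),
repost-aware text cleaning, aggregation of posts into person-day and
by-day emotional trajectories for a locked-down and a comparison group,
and piecewise multilevel growth models of the immediate and longer-term
emotional response to the lockdown event. Because the original microblog
corpora cannot be redistributed, the package ships a first-class
synthetic-data generator whose default regime is the published study
conditions, so every stage is testable end to end without any download.

## Affect scoring

Each lexicon word carries a valence in [-4, +4] (pleasantness, bipolar)
and an arousal in [0, 8] (activation, unipolar). A post's score is the
frequency-weighted mean over matched emotion words:

    valence(post) = sum_w c_w * v_w / sum_w c_w

and identically for arousal, where `c_w` counts occurrences of lexicon
word `w`. Posts with no lexicon match are *missing* and are excluded
from all downstream analyses. Quadrants of the circumplex plane are
assigned with strict inequalities — pleasant (v > 0) vs unpleasant
(v < 0), high (a > 4) vs low (a < 4) arousal — with exactly-neutral
valence or exactly-moderate arousal forming a residual class. The
corpus-level valence-arousal relation is summarized by an OLS quadratic
regression of arousal on valence (the "V shape": both strongly pleasant
and strongly unpleasant posts tend to be activated).

### Tokenization

Emotion words are extracted by deterministic forward maximum matching
against the lexicon keys: scan left to right; at each position consume
the longest lexicon word starting there, else advance one character.
A general-purpose statistical segmenter would be an alternative; maximal
matching was chosen because it is fully reproducible, dependency-free,
and is the canonical dictionary-matching baseline for unsegmented text.
The practical difference matters only for lexicon words that a
segmenter would split or merge; the package's scope is scoring against
a fixed lexicon, for which maximal matching is exact by construction.
Text is canonicalized first (full-width digits/latin to half-width,
latin lowercased); no stemming, no negation or intensifier handling —
the weighted-average scoring scheme has none.

## Cleaning

Reposts concatenate the reposting user's own comment with prior users'
comments, delimited by `//@username:` markers. Only the reposting
user's own comment is scored; when it is blank, the prior users'
comments stand in for it (users repost what they endorse) and the
record is flagged. Hashtag markers, @-mentions and URLs are stripped.
Paired hashtags keep their interior text by default, since tag
interiors are ordinary content (emotion words frequently appear inside
campaign tags); this is configurable. Calendar dates are bucketed in a
configurable civil time zone, UTC+8 by default. Records with
unparseable timestamps are collected as errors, never fatal to a batch.

## Cohorts, groups, aggregation

The study window runs 2020-01-09 to 2020-02-06 with the event on
2020-01-23. The longitudinal cohort rules ("dataset2") drop posts
outside the window, posts with missing scores, users with a single
scored post, and users lacking at least one scored post before the
event and one on/after it. "Before" means strictly before the event
date; the event day itself is post-event, because the lockdown took
effect that morning and the day is analyzed as the response day. Every
removal is counted in an audit dict whose entries plus survivors sum to
the input size.

Users are grouped by post-event geolocation: inside the Wuhan bounding
box → locked-down group (dummy code 1); outside the Hubei box →
comparison group (code 0); inside Hubei but outside Wuhan → excluded,
because other Hubei cities entered lockdown on their own staggered
schedule; unlocatable users → excluded. Region membership ships as
named bounding boxes (a Wuhan box nested in a Hubei box) rather than
administrative polygons — adequate for synthetic data and honest about
the imprecision of user-selectable geotags. Only post-event records
are informative (movement out of the locked-down city was no longer
possible); pre-event geotags are ignored, and ungeotagged posts are
uninformative rather than disqualifying.

Two aggregation levels: the *person-day* score averages one user's
scored posts within a date (the models' level-1 observation); the
*by-day* score averages person-day scores across users, one vote per
user per day regardless of posting volume. A post-weighted by-day
variant is available but is not the default. Descriptive statistics per
group report the moment estimators g1 (sample skewness) and g2 (excess
kurtosis), with the conventional acceptability bounds |g1| <= 2,
|g2| <= 7 flagged; the excess convention is used because the published
kurtosis values against a +/-7 band are only consistent with it.

## Piecewise multilevel growth models

Time is coded as four slopes (defaults in parentheses): slope 1, the
pre-event run-up (01-20 start); slope 2, the one-day jump onto the
event day (01-22 start); slope 3, the one-day change off the event day
(01-23 start); slope 4, the longer-term post-event trend (01-24 start).
A slope is 0 on/before its start, increments by one per day inside its
window, and holds at its maximum afterwards. The hold-at-max convention
is the standard piecewise-growth coding; a slope 1 that kept increasing
would be collinear with slope 4. Under this coding slopes 2 and 3 are
0/1 event indicators, so the fitted mean change from 01-22 to 01-23 is
exactly the slope-2 coefficient (plus its location interaction in the
locked-down group) — an identity the tests assert on noiseless data.
Fitting starts at 01-20 because earlier days are too thin; the pipeline
additionally drops days observed by fewer than 50 users by default
(configurable; the library's fit functions leave this off so small
examples remain fittable).

Person-day scores are modelled with linear mixed models (users as
level-2 units): an "empty" random-intercept model yields the ICC
(between-person variance over total variance); model 1 adds the four
slopes with random effects on slopes 2 and 3 and location moderation of
both; model 2 instead gives slope 4 the random effect and moderation.
Random effects within a model are correlated (unstructured covariance)
— forced by the published likelihood-ratio degrees of freedom, which
count dropped covariances. Estimation is REML (statsmodels `MixedLM`);
an L-BFGS first attempt falls back to more conservative optimizers when
the line search steps through a singular covariance, and any fit whose
covariance is numerically singular is flagged, never silently accepted.

Fixed-effect p-values are Wald z against the normal reference — the
minimal-assumption default given that no denominator-df method is
stated for the published tables; with thousands of users the difference
from Satterthwaite-style corrections is negligible. Random-effect
LRTs compare nested random structures at identical fixed effects (valid
under REML), with chi-square equal to the difference in REML -2
log-likelihoods floored at zero and df equal to the number of
variance/covariance parameters dropped: removing one correlated random
term from a q-term structure drops q parameters (one variance, q-1
covariances), giving df 3 in model 1 and df 2 in model 2. For the empty
model the random-intercept LRT drops exactly one variance parameter, so
the package reports df 1; the published empty-model chi-square is
printed with df 4, which does not match any parameter count for
dropping a lone random intercept, and the package deliberately reports
its own counting rule instead. The nominal chi-square reference is
used; boundary conservatism (variance >= 0) is noted, not corrected.

## The synthetic-data generator

The generator runs the level-1/level-2 growth model forward. Defaults
are the published regime: 1,236 locked-down and 12,714 comparison
users; the published fixed-effect estimates and random-effect SDs
(immediate-response model: intercept/slope-2/slope-3 SDs 0.452 / 0.259
/ 0.260 for valence); residual SDs derived by inverting the ICC
identity (between-person variance 0.332 and ICC 0.134 give residual SD
1.465 for valence; 0.252 and 0.098 give 1.523 for arousal); posting
activity ~0.14 active days per user-day, matching the published totals
(57,685 posts by 13,950 users over 29 days), with the cohort guarantee
of at least one pre-event and one post-event active day. Random-effect
correlations default to 0 because the published tables print none.
Valence and arousal are generated from separate models with independent
random effects. Group sizes are the usual override for desk-scale runs;
tests use 100-600 users.

Post text is rendered from a synthetic lexicon (default size 7088, the
size of the real one): valence uniform on [-4, 4]; arousal a convex
quadratic in valence (coefficients 2.156 / 0.368, the published
corpus-level curve) plus Gaussian noise (SD 1.2), clipped to [0, 8].
Words use three pairwise-disjoint character pools (initial,
continuation, filler) and are kept prefix-free, so forward maximum
matching recovers every rendered token multiset exactly — the
generator's token bookkeeping, and hence prevalence ground truth, is
exact, not approximate.

Each post's word multiset (3-12 words) is chosen so its weighted mean
lands within a declared tolerance (0.05) of the post's target — the
person-day value projected into the lexicon's *renderable region*: the
convex hull of the lexicon's score points eroded by a margin (0.15),
intersected with a local-density criterion (a target must have several
words nearby to be expressible as a short post's mean). Targets in
sparse territory are stepped toward the nearest well-covered word until
a maximum-length rendering verifiably meets tolerance; the verified
token set is kept as a fallback for every post of that person-day, so
closure of render → clean → score → person-day holds by construction.
The realized rendering target is recorded in the ground truth, and the
closure tests compare pipeline output against it. Noise wrapping
(repost chains with lexicon-word decoys in the prior comments, paired
hashtags around a token, mentions, URLs, non-lexicon filler inserted at
token boundaries) exercises every cleaning path; geotags are drawn
inside each group's region box.

What the generator does *not* emulate: linguistically plausible
sentences, topic structure, censorship dynamics, duplicate/spam posts,
emoji, or any dependence of posting intensity on emotional state
(activity is missing-completely-at-random). Passing tests therefore
demonstrate correctness of the pipeline's mechanics and estimators
under the stated generative model, not robustness to the messiness of
real microblog text beyond the noise forms listed above.

## Numerical choices

- Mixed-model convergence: statsmodels defaults at maxiter 500;
  optimizer fallback chain rejects non-finite log-likelihoods.
- Quadratic regression requires >= 4 points and >= 3 distinct valence
  values; rank-deficient designs are an error, and R^2 is checked
  against 1 - SSE/SST to 1e-10 in the tests.
- Top-k word-frequency ties break by code-point order, for determinism.
- Rendering problem sizes in the tests (100-600 users, 18-29 days) were
  chosen as the smallest scales at which the recovery and closure
  properties are informative; all scale parameters are config fields.
- Degenerate inputs: constant data yields SD 0 with undefined
  skew/kurtosis reported as missing; empty text scores as missing;
  single-observation groups and empty lexica are errors.

## Known limitations

- Bounding-box geography misclassifies locations near province borders;
  real administrative polygons are out of scope.
- Wald-z p-values are anti-conservative for very small user counts; the
  intended regime is hundreds of users or more.
- The lexicon scoring has no negation or intensifier handling, so
  "not happy" scores as "happy" — a faithful property of the
  weighted-average scheme, inherited deliberately.
- Forward maximum matching is greedy; a text where a shorter match
  would enable a better global segmentation is resolved greedily, by
  design.
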
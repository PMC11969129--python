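# Methods

This note records the models, parameter choices and numerical decisions
behind `gadprofiler`, and what the synthetic validation does and does not
establish.

## Cohort construction

Cohorts mirror the self-reported-diagnosis protocol: a case-insensitive
regex finds the diagnosis statement ("i was diagnosed with generali[sz]ed
anxiety disorder", the parenthetical abbreviation optional, whitespace
flexible); heuristic flags (quotation marks around the span, reported-speech
markers, third-person pronouns, negation) populate a review worksheet but
never exclude automatically — verification is a human step by design.
Filters are applied in a fixed order: (1) users below 80 % English tweets
are dropped; (2) survivors lose their non-English tweets; (3) users below
100 remaining tweets are dropped. The order matters (a user can pass the
fraction rule yet fail the count rule only after non-English removal) and is
logged per exclusion, so |input| = |kept| + |logged| always holds. Language
detection is deliberately pluggable: per-tweet tags are trusted when present
(the simulator writes them); otherwise a classifier callable must be
injected. Users present in both groups are removed from control only.
De-identification is a stable salted SHA-256 hash over user, tweet and
reply-target ids.

## Two token streams

Lexicon scoring consumes *raw* tokens (post-cleaning, stop words retained,
no lemmatization): several scored categories — tentativeness,
discrepancy, differentiation, certitude — live largely in stopword-like
function words and would be zeroed by a stopword pass. The topic model
consumes lemmatized, stopword-free tokens. The `@user` mention placeholder
is excluded from both analysis streams (an anonymized mention carries no
content); hashtag words lose their `#` and stay in the text stream, since
tag words carry theme signal. The word-count denominator for category
percentages counts tokens with at least one alphanumeric character, plus
punctuation-only tokens that match a dictionary entry (emoticons), so
percentages are always bounded by 100.

The default tagger and lemmatizer are small shipped lookup tables with
suffix rules (tagger) and a (token, tag) → lemma map with (token, NOUN) and
identity fallbacks. This favors exact reproducibility over linguistic
accuracy at desk scale; both components accept injected replacements with
the same signatures. Seed words are passed through the same normalization
at load time so surface forms ("kids") meet their document lemmas ("kid")
in the model vocabulary.

## Dictionary scoring

Matching semantics: literal entries match whole tokens, `stem*` matches any
token with that prefix, all matches count once per token per category, and a
token in k categories contributes to all k. Prefix entries live in a
character trie purely as an optimization — tests assert indistinguishability
from a brute-force entry-by-entry counter on randomized lexicon/document
pairs. Scoring runs over each user's concatenated history (user-level
means), not per tweet; the alternative is a one-line change and the choice
is recorded in run metadata. The shipped 23-category dictionary is an open
fixture for tests and demos, explicitly not LIWC; its category contents were
chosen to be disjoint from the default theme vocabularies (the anxiety
category carries nervous/panic/fear*, while worry/anxiety are theme words)
so linguistic and thematic recovery cannot confound each other. A test
enforces this disjointness.

## Seed-guided topic model

Collapsed Gibbs LDA with symmetric priors. Guidance is initialization-only:
a seed-word token starts in its guided topic with probability π
(seed confidence, default 0.7) and uniformly at random otherwise; the
sampler conditional is the standard unbiased collapsed form. Defaults:
2 background topics besides the guided ones, α = 0.1, β = 0.01,
500 iterations with 100 burn-in, counts averaged every 10th post-burn-in
sweep for φ/θ estimation; argmax ties break to the lowest topic index;
vocabulary pruning keeps words with document frequency in [5, 0.5·D], seeds
always retained, indexed by df descending then lexicographically. The sweep
kernel is one plain-Python function JIT-compiled with numba; the interpreted
path is retained and a test asserts the two produce bitwise-identical
assignments. All randomness enters through pre-drawn uniforms from a single
seeded generator, so runs are exactly reproducible.

Documents are individual tweets (theme prevalence is denominated in tweets
per user). The per-tweet assignment rule is this package's own
construction, since "a tweet has a theme" needs an operational definition:
a tweet expresses guided theme k iff its posterior-mean share of modeled
tokens in topic k is ≥ τ (default 0.5) and it has ≥ 3 modeled tokens.
The min-token floor keeps short noisy tweets from inflating prevalence;
both knobs are configurable and recorded in output metadata. The
"themes per tweet" frequency is the mean cardinality of these sets.

## Statistics

Effect sizes use the pooled-SD (Student) form of Cohen's d, reported
unsigned, graded small < 0.20 ≤ medium < 0.50 ≤ large. This form reproduces
published worked-example values from printed group summaries (nine are
frozen in tests at two decimals). One-tailed two-sample t tests require a
direction declared per feature in configuration *before* testing — inferring
direction from the data would invalidate p — and a shipped defaults file
encodes elevated content features and the withdrawal-pattern behavior signs.
A Welch variant and two-sided alternative are available by flag. No
multiple-testing adjustment is applied by default; Benjamini–Hochberg
q-values are an optional extra column. Correlations are Spearman by default
(Pearson by flag), computed within group over pairwise-complete users, with
cells under 3 complete pairs reported missing. The follower–followee ratio
with zero followees is missing, never infinite, and drops out pairwise.

Behavioral conventions: retweets count inside the tweet total (the ratios
are otherwise ill-defined); quote-style reply-retweets count as retweets
only, keeping categories disjoint; per-day rates divide by the observed
tweet span (floor of the day span plus one, minimum one) rather than account
age, because retrieved histories are truncated; mention occurrences are
counted per tweet, with a variant that drops the single leading reply-target
mention in replies.

## Synthetic study conditions

The generator's defaults are the study conditions: group sizes 1316/1463;
tweets per user normal (2559, 1316) / (2697, 918) truncated at the
100-tweet filter floor; per-user category usage rates at linguistic-table
scale for all 23 categories; theme prevalences 10/5 (symptoms), 11/7
(life problems), 13/7 (relationships), 9/4 (feelings) percent of tweets;
behavior flag means 0.41/0.29 (reply), 0.29/0.49 (retweet), 0.087/0.16
(hashtag), 0.32/0.51 (mention) with Beta-distributed between-user spread
(concentration 20); heavy-tailed log-normal follower/friend/listed/favorite
counts. Three designated categories carry exact planted effects —
curiosity d = 1.2, communication d = 0.8 (control above diagnosed),
negative tone d = 0.4 — chosen as the highest-rate categories so multinomial
token noise barely attenuates the realized d.

Design choices that make planted quantities exactly recoverable:

* **Stratified planting.** Per-user rates and flag probabilities are drawn
  by randomly permuted quantile stratification, so realized group means and
  SDs equal their targets up to quadrature error even at n = 200.
* **Severity factor.** Each diagnosed user has s ~ N(0,1); theme
  probabilities and designated behavior flags are tilted by a logistic link
  in s (loadings 0.5 for themes; 0.6/0.4/0.3 for reply/hashtag/mention),
  with intercepts calibrated by Gauss–Hermite quadrature so marginal means
  stay on target. Control users have loading zero. This is the mechanism
  behind diagnosed-group-specific theme × behavior correlations.
* **Mutually exclusive themes.** Per tweet, at most one theme is drawn
  (categorical over themes plus none). Independent per-theme draws would
  make ~30 % of themed tweets multi-theme, and the τ = 0.5 share rule
  structurally drops those, biasing prevalence recovery by several points.
* **Theme-independent category shares.** Every token is a category word
  with its planted per-category probability over *all* tokens; only the
  remainder is split between theme words (share 0.9 inside themed tweets)
  and filler. Realized category percentages are therefore independent of
  theme prevalence, which differs by group.
* **Token counts** are uniform 5–25 per tweet — tweet-scale documents with
  enough tokens for the 3-token assignment floor. Hashtags are planted by
  prefixing `#` onto an existing token (so tag stripping restores the word
  and counts are undisturbed); mentions insert an `@handle` token that
  cleaning neutralizes; retweet/reply status is metadata-only.

What passing recovery tests shows — and does not. The generator emits
structured draws from disjoint vocabularies: no grammar, no polysemy, no
topic drift, no lexical overlap between categories and themes unless the
overlap knob is turned. Recovery therefore validates the pipeline's
bookkeeping, estimators and inference (that planted signal at realistic
scale survives cleaning, tokenization, scoring, sampling and testing
undistorted), not the construct validity of dictionary categories or topic
themes on real language.

### Problem sizes used in tests and the acceptance script

Recovery runs use a documented desk-scale preset of the same study
conditions: 200 users per group, tweets per user (150, 30), LDA
150 iterations / 50 burn-in. At these sizes each user carries ≈ 2250 words,
so the residual multinomial attenuation of a planted d is 4–7 % — visible in
the worked example (1.167 measured vs 1.2 planted) and well inside the
±0.15 recovery tolerance; theme prevalences recover within ~1 point of
their targets and flag means within ~0.015. The full-scale defaults
(≈ 7 M tweets) remain available through `SimulationConfig()` for longer
runs. The type-I-error calibration uses 2000 null replications at n = 50
per group, giving a Monte-Carlo standard error of ≈ 0.005 around the
nominal 0.05.

## Known limitations

* The shipped tagger/lemmatizer/stop list are compact lookup resources, not
  general English NLP components; on real prose an injected tagger and
  lemmatizer are advisable.
* The open fixture dictionary is small (~250 entries); scores on real text
  are not comparable to proprietary word-count tools.
* Guidance is initialization-only; with very diffuse seeds or heavy topic
  overlap the sampler can drift from the seeded labeling (label switching
  is only anchored by the seeds).
* The review-flag heuristics are worksheet aids with no validated
  sensitivity/specificity; they do not replace human verification.
* Per-day rates depend on the observed-span convention; switching the
  denominator to account age changes their scale.
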
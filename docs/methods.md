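# Methods

This note documents the models and procedures implemented in `traceclust`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical choices that affect results.

## Data model and preprocessing

The atomic record is a trace event: an opaque actor id, a calendar date
(day resolution — platforms typically truncate timestamps for privacy), and
a target–action token such as `submission>graded`. Tokens are canonicalized
to `target>action` with whitespace around the separator tolerated; dates
are accepted in ISO (`2019-06-17`) or day-first (`17.6.2019`) form, with
day-first the default because that is how institutional exports usually
print dates. Weeks follow ISO-8601 numbering, matching European
institutional calendars where a January start makes "weeks 1–22" the spring
semester.

Two filters precede all modeling:

1. **General-use removal.** Six tokens — `user>loggedin`, `user>loggedout`,
   `notification>sent`, `notification>viewed`, `course>viewed`,
   `course_module>viewed` — reflect generic platform use rather than a
   specific work task and are removed entirely. The list is configurable.
2. **Low-activity-week removal.** Any actor-week with fewer than 25
   remaining events is dropped as a whole; 25 is kept while 24 is dropped
   (a strict lower bound). The threshold is applied **after** general-use
   removal: the removed tokens carry no task information, and the threshold
   is meant to gate meaningful task activity. Both filters are idempotent
   and order is fixed (removal first); a test pins the case where an
   actor-week has 30 events of which 10 are general-use and must be
   dropped.

## Documents and topic model

Each surviving actor-week is one bag-of-words document over the vocabulary
of distinct tokens (sorted lexicographically for determinism; raw counts,
no TF-IDF — occurrence counts are the modeled quantity; no frequency floor
is applied, though `min_token_count` exists as a config hook). Token counts
are conserved exactly: the sum of document totals equals the number of
surviving events.

LDA is fit with batch variational Bayes (scikit-learn) under symmetric
Dirichlet priors α = η = 1/K; the estimation algorithm and priors are
exposed in config since different choices are defensible. Fits are
deterministic given the seed. The default iteration cap is 20 batch EM
steps: on the corpus sizes this package targets the variational bound is
effectively converged well before that, and model-selection grids multiply
whatever the per-fit cost is by |K-range| × restarts.

**Likelihood and BIC.** The model score is the variational lower bound on
the corpus log-likelihood (the standard proxy for this estimator; the exact
marginal likelihood is intractable). Each fit is scored with

    BIC = −2·logL + k·ln(n),  n = total token count.

The free-parameter count `k` is a genuine design choice, since LDA has both
corpus-level and document-level quantities. The default counts only the
topic-word parameters, `k = K(V−1)`: the per-document topic mixtures are
latent variables of the generative model, and counting them (`k += D(K−1)`,
available as `bic_param_mode="full"`) penalizes the document count twice —
once through `n` and once through `k` — which in practice collapses
selection to the smallest K considered.

**Model selection** fits every (K, restart) pair — restart seeds are
`master_seed + i`, logged in the report — and selects the minimum-BIC fit.
Restarts are interpreted as *per topic number*. Automatic min-BIC is the
default; because a human analyst may prefer a different low-BIC model after
inspecting topics, the report lists the best candidates with their top
tokens, and `force_n_topics` pins K manually.

## Themes and processes

Themes are a manual grouping of topics into a few interpretable categories
(e.g. Evaluation, Courses, Progress tracking, Situation tracking, Final
grading). The map is user configuration (YAML); unassigned topics fall into
the catch-all "Others". A document's theme distribution is the sum of its
topic probabilities within each theme — mass is conserved exactly, and
aggregation commutes with averaging (linearity, asserted to 1e-12). When no
map is supplied the pipeline uses raw topics as themes (identity map) and
flags it; this is appropriate when the topic number is small.

An actor's process over a week window (default: weeks 1–22 of a year, the
spring semester) is `(P_i(t), C_i(t))`: the weekly theme distribution,
defined exactly on weeks with a surviving document, and the weekly event
count, zero elsewhere. Weekly averages over actors are unweighted over
*active* actors by default (an activity-weighted variant is a flag):
inactive actors are flagged rather than imputed as zeros.

## Dissimilarity

    d_ij = Σ_t w_ij(t)·JS(P_i(t)‖P_j(t)),
    w_ij(t) = C_i(t)C_j(t) / Σ_τ C_i(τ)C_j(τ)

JS is the Jensen–Shannon *distance* (square root of the divergence), with
base-2 logarithms so single-week distances and hence `d_ij` lie in [0, 1].
Both choices are switchable (`log_base`, `sqrt`); changing the base
rescales but never reorders single-week comparisons. Zero probabilities
need no smoothing (0·log 0 = 0); probabilities are used as-is.

`d` is a weighted average with *pair-specific* weights, so it is not a
metric: the test suite constructs a 3-actor instance (two deterministic
opposites plus a bridge actor whose co-activity concentrates on the week
where it agrees with each) violating the triangle inequality. Complete
linkage does not require metricity.

Pairs with no co-active week have no defined value. Default policy assigns
the maximal dissimilarity 1.0 (such actors share no observed behavior) and
records the pair; a `drop` policy removes the involved actors instead.

## Clustering

Complete-linkage agglomerative clustering is implemented directly (not via
a library call) so the tie-break is pinned: among pairs at the minimal
dissimilarity, the lexicographically smallest cluster-id pair merges first
(leaves 0..n−1 in input order, merge m creating id n+m). This makes merge
sequences bit-reproducible; heights agree with SciPy's implementation on
distinct-height inputs and with a naive O(n³) re-computation oracle on all
test fixtures including ties. Complete linkage guarantees non-decreasing
merge heights on any symmetric non-negative input.

Flat clusters are cut by count (apply the first n−k merges; exact) or by
height (apply merges at height ≤ threshold). `k` defaults to 6, a typical
operating point for this analysis; a silhouette-versus-k table is emitted
as a diagnostic but never auto-selects, since no automatic criterion for k
is part of the method. Each week window (e.g. spring 2019 and spring 2020)
is clustered independently by default; a joint mode would concatenate
windows into one sequence.

## Reporting and peak weeks

Cluster summaries are unweighted means over active actors per week; weeks
where no member is active are flagged ("no data") rather than imputed.
Peak weeks operationalize "the climax of an increasing trend after which
activity decreases": week t is a peak of a theme group's share series s iff
s(t) > s(t−1), s(t) > s(t+1) (strict — plateaus are not peaks), endpoints
are never peaks, and the peak's prominence is at least `min_prominence`
(default 0.02, i.e. two percentage points of theme share; a sensitivity
mode at several thresholds is available by calling `detect_peaks` with
different values). The default theme group is {Evaluation, Final grading},
the grading demand. Figures are stacked-area charts with fixed theme color
order, and every figure's numbers are also emitted as CSV so plots are
auditable (round-trip equality within 1e-12).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
planted ground truth emitted as a JSON sidecar (never embedded in the log):

* **Cluster structure.** Actors are assigned round-robin to clusters; each
  cluster has its own piecewise-linear weekly theme-weight trajectories,
  normalized per week.
* **Counts.** Weekly task-event counts are negative binomial (mean 120,
  dispersion 2 by default — weekly activity counts in real logs are
  strongly overdispersed, and a dispersion of 2 gives the heavy right tail
  seen in count data of this kind while keeping nearly all weeks above the
  25-event filter).
* **Tokens.** Each task event draws theme → topic (uniform within theme) →
  token from the topic's word distribution; default topic-word
  distributions partition the task vocabulary into disjoint uniform blocks.
* **General use.** Per actor-week, general-use events are injected with a
  Poisson count calibrated so their expected fraction equals
  `general_use_rate` (default 0.25 — general platform actions are a large
  minority of raw events); the planted topics place no mass on the six
  general tokens, so the removal filter removes exactly the injected
  events, which the tests exploit.
* **Low-activity weeks.** With probability 0.05 an actor-week's task count
  is resampled uniformly below the 25-event threshold, exercising the
  filter.
* **Dates.** Week w is a concrete Monday (consecutive ISO weeks from week
  1 of the start year) plus a uniform day offset, so date→ISO-week
  assignment round-trips the generator's week indices exactly.

What the generator does **not** emulate: real vocabulary sizes (hundreds of
token types), actor heterogeneity in overall volume, within-week
day-of-week patterns, gradual drift of topic content, and non-disjoint
topic supports. Passing the recovery tests therefore shows the pipeline
correctly recovers structure *of the kind it assumes*, at moderate noise —
not that real logs contain such structure.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use deliberately modest sizes chosen to make the
properties sharp: topic recovery and BIC selection use corpora of 200
documents × 40 token types × ~200 tokens per document drawn from 4
disjoint-support topics (selection grid K = 2..8, 5 restarts); end-to-end
recovery uses 3 clusters × 10 actors × 22 weeks with well-separated
trajectories (85% of weekly mass on the cluster's own theme), selection
grid K = 2..6 with 3 restarts. With disjoint supports and these volumes,
recovery is expected to be near-perfect; the adjusted-Rand threshold of
0.9 leaves room only for boundary noise.

## Known limitations

* BIC for LDA rests on a likelihood *bound* and a debatable parameter
  count; it is a pragmatic model-comparison device, not a calibrated
  posterior quantity. Cross-checking with held-out perplexity or coherence
  is out of scope.
* The dissimilarity ignores weeks where either actor is inactive; two
  actors with complementary schedules can look deceptively similar or end
  up as an undefined pair.
* The theme step is manual by design; results downstream depend on that
  human grouping.
* Peak detection operates on cluster *means*; individual actors' peaks may
  differ.
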
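# Methods

This note documents the models, algorithmic choices, defaults and known
limitations of `narrec`.  Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

Word indices are 0-based; events are half-open `[start, end)` intervals in
word coordinates; times are integer milliseconds (annotation vectors are
sampled at 1000 Hz).  Tokenization splits on whitespace, strips edge
punctuation, keeps internal hyphens and apostrophes, and lowercases;
sentences are detected from terminal `. ! ?`, with a fallback of one
sentence per 12 words for unpunctuated input.  The stop-word list is frozen
inside the package so count matrices are environment-independent.

## Topic trajectories and event segmentation

**Windows.** A transcript of n words is covered by windows starting at
0, s, 2s, …, each w words long (final window truncated; a transcript
shorter than w gives one window).  Defaults w = 55, s = 21, K = 40 — the
hyperparameters selected by grid search against annotator ground truth in
the study the pipeline reproduces, applied to all stories.

**LDA.** Fitted per story by batch variational inference
(`sklearn.decomposition.LatentDirichletAllocation`, 50 iterations,
default priors, fixed `random_state`).  Recalls are *transformed* through
the story's fitted model, never re-fitted, so story and recall event
vectors live in one topic space.  Windows with no in-vocabulary tokens get
the uniform mixture with a warning.  The variational objective is
multi-modal: occasionally a fit merges two genuinely distinct themes, which
is the dominant failure mode of downstream boundary recovery.  An optional
`n_init` refits from several seeds keeping the best evidence bound; the
default is a single fit because in our recovery experiments bound-selected
restarts were no better (the bound rewards fit to word counts, not event
separation).

**HMM.** Left-to-right, E states, transitions stay or advance by one with
advance probability (E−1)/(T−1) (T = number of windows), forced start in
state 0 and end in state E−1.  Emission log-density is −‖z(xₜ) − z(mₑ)‖²/2
on per-dimension z-scored topic vectors — an isotropic Gaussian with shared
variance, standard for event segmentation of topic/neural trajectories and
free of extra parameters.  Fitting alternates constrained forward–backward
state posteriors with posterior-weighted mean re-estimation until the
log-likelihood change is below `tol` (1e-4) or `max_iter` (100); the
log-likelihood is non-decreasing (EM with fixed variance).  Assignment is
the per-window argmax posterior, made monotone by a cumulative maximum; if
that ever skips a state the Viterbi path (which must visit every state) is
used instead.

**Boundary words.** An event's boundary is the start word of its first
window **plus half the window overlap, (w − s)//2**.  A window is assigned
to the new event once most of its span lies past the true change point, so
the bare start word systematically undershoots by about half the overlap;
the correction is unbiased in expectation and vanishes for non-overlapping
windows.  This was measured directly on synthetic stories (errors of ~10–13
words at w = 25, s = 5 without the correction, ~0–4 with it).

**Choosing E.**  The number of events per story is not, in general, known.
`select_num_events` segments at each candidate E and scores
(mean within-event Pearson correlation of window vectors) −
(mean correlation across adjacent events), taking the smallest argmax.
Stories default to candidates 2..min(50, T), recalls 1..min(20, T).  The
criterion recovers planted event counts under moderate window overlap
(w = 25, s = 12 in the tests) but tends to over-segment with heavy overlap
(s ≪ w), because windows straddling a boundary form their own coherent
mini-clusters.  Over-segmentation is benign for recall scoring — split
recall events still match the correct story event, and duplicates collapse
in the binary recall matrix — while under-segmentation loses events, which
is why the recall-side candidate range starts at 1 but the criterion is
otherwise left symmetric.

**Grid search.** For each (w, s, K) with s ≤ w the story is segmented with
E fixed to the ground-truth event count and scored by boundary F1 at
`tol_words` (default 10 ≈ 5 s at the study's ~2 words/s, the spacing
events are assumed to respect).  Ties break toward smaller K, then w, then
s (prefer simpler models).

## Ground truth from button presses

Presses are binned into half-open 5 s bins (any press = 1).  The null
shuffles each annotator's binned vector across time — by default an
independent circular shift per annotator per iteration, which preserves
press counts and within-vector run structure; full per-annotator
permutation of bins is available as `method="permute"`.  Per-bin null
averages are pooled over iterations into a single distribution per story;
the threshold is its (1 − α) quantile and a bin is significant when the
observed agreement strictly exceeds it.  Because the agreement statistic is
a mean of n binary values, strict exceedance is slightly conservative at
small n (ties at the threshold); at the study's scale (205 annotators) the
realized false-positive rate is within sampling error of α, which is what
the calibration tests check.

Consecutive significant bins are grouped into runs — agreement around one
perceived boundary regularly spills across a bin edge, and per-bin peaks
would emit doublet boundaries one sentence apart.  Per run, the 1000 Hz
peak of the annotator average (earliest ms on ties) is mapped to the word
with the nearest onset and snapped to the nearest sentence start by word
distance (earlier sentence on ties); duplicates merge and word 0 is always
prepended (the story start is not a discoverable boundary and is never
scored).

Boundary F1 matches predicted to true boundaries greedily by increasing
|distance| within `tol_words`, one-to-one; precision = matched/|pred|,
recall = matched/|truth|.  Greedy matching is the definition, not an
optimization — it is what the tolerance-F1 literature uses and is
deterministic.

## Recall scoring and inference

Matching is argmax Pearson correlation over the K topic dimensions, ties
toward the earlier story event; there is no minimum-correlation floor by
default (a `min_r` option exists for sensitivity analyses).  Multiple
recall events may map to one story event; the matrix is binary, so
duplicates collapse — events are scored recalled/forgotten, not counted.

Recall probability is the column mean with percentile bootstrap 95% CIs
over participants (default 10,000 resamples; CIs are clipped to bracket
the point estimate, removing sub-resolution resampling noise).
Significance uses a within-participant event-order permutation null pooled
across events into a single threshold per story (97.5th percentile for the
2-tailed α = 0.05); the same discreteness caveat as above applies and is
quantified by the calibration tests at large n.

## List-learning statistics

PFR excludes (and counts) participants with empty recalls; the curve is the
distribution of the story position of each participant's first recall
event, with bootstrap CIs over participants.  Lag-CRP drops lag-0 pairs
(two recall events matched to the same story event — undefined in CRP
tradition; a `keep_lag0` flag retains them), divides each participant's
per-lag counts by their total retained transitions, and averages across
participants with at least one retained transition, all participants
weighted equally.  The classical availability-conditioned CRP is available
as `availability=True` for comparison.  Permutation p-values shuffle each
participant's recall order uniformly and use the add-one rule
p = (1 + #{null ≥ obs})/(1 + n_perm), so the minimal attainable p is
1/(n_perm + 1).

## Semantic networks and the centrality effect

The default embedding backend is TF-IDF over event texts followed by
truncated SVD to d = 128 (falling back to raw TF-IDF when fewer than two
components are possible, which keeps disjoint-vocabulary texts orthogonal),
rows L2-normalized.  It is deliberately offline and deterministic; heavy
sentence encoders plug in as any `texts → matrix` callable.  Edges keep
cosine ≥ 0.35 (the threshold used for the published network figures);
centrality is the *mean* unthresholded cosine to all other events — mean
rather than sum so values are comparable across stories with different E,
and threshold-free by construction.

The centrality → recall effect is estimated on long-format observations
(participant × event, recalled ∈ {0,1}, centrality z-scored within story —
z-scoring makes the slope comparable across stories and invariant to
affine rescaling of raw centrality).  The model is linear mixed-effects
with a random intercept per participant, plus a story variance component
when several stories are pooled; statsmodels' MixedLM does not support
fully crossed random effects, so story enters as a variance component
within the participant grouping — with each participant seeing few
stories this is an approximation, reported as such in the result's
`grouping` field.  A Bayesian binomial mixed GLM (`model="logistic"`) is
available; the linear model is the default because a linear
probability-scale slope is the replication target.  Degenerate inputs
(constant centrality within every story) return NaN with a warning rather
than a spurious zero.

## Synthetic-data generator

The generator defines the package's study conditions.  Stories: E events,
word counts uniform on `words_per_event_range` (default 80–120), T = E
topics as sparse Dirichlet(0.1) draws over a vocabulary of 20·T integer
tokens ("w0001"), event mixtures Dirichlet(`topic_concentration`, default
0.05) rotated so event e's dominant topic is e mod T (adjacent events are
always dominated by different topics; low concentration gives the
near-one-hot, well-separated regime used by the recovery tests at 0.005).
Sentences are 8–15 words, never straddle an event boundary (so planted
boundaries are sentence starts), and a short tail (< 8 words) merges into
the previous sentence so snapping targets are never degenerate.  Word
timing is a constant 500 ms per word (~10 words per 5 s, matching the
spacing assumption behind the 5 s annotation bins), 450 ms voiced + 50 ms
gap.

Recalls: each event enters the recalled set by an independent Bernoulli
(`p_recall`, scalar or per-event; `primacy_boost` multiplies event 0's
odds).  The first produced item is the earliest recalled event with
probability `p_first_is_first` (otherwise uniform over the remaining
recalled events — this makes the planted first-recall probability exactly
recoverable when every event is recalled); each subsequent transition goes
to the nearest not-yet-produced event in the forward direction with
probability `contiguity`, otherwise to a uniform random remaining event.
Recall text draws `words_per_recalled_event` words (default 30) from each
produced event's topic mixture, with a `noise_level` fraction replaced by
uniform vocabulary draws.  Annotators press at each true boundary onset
with probability `p_detect`, Gaussian jitter (`jitter_sd_ms`, truncated to
the story duration), plus Poisson false alarms (`false_alarm_rate_hz`).

What the generator does **not** emulate: disfluencies, fillers,
paraphrase, transcription error beyond uniform word noise, semantic
similarity structure between events (topics are near-orthogonal), or any
planted relation between centrality and recall.  Passing recovery tests
therefore demonstrates that the pipeline's machinery is correct and
calibrated under its own generative assumptions — not that the topic model
is adequate for real narrative text, which is exactly what the published
grid search against human ground truth had to establish.

## Problem sizes and defaults used in validation

The acceptance script and tests run at desk scale, chosen to keep each
recovery property sharply testable: stories of 6–8 events × 80–120 words,
windows w = 25, s = 5 (s = 12 where event-count selection is exercised),
K = 12 topics, 75–500 synthetic participants per property, 205 annotators
(the published annotator count) × 98 bins for boundary calibration, and
1000 participants × 30 events for flag-rate calibration, where the binary
mean statistic is effectively continuous.  Permutation/bootstrap sizes in
the validation runs are 500–1000 (the analysis defaults are 10,000, as
published).

## Known limitations

- Batch variational LDA occasionally lands in an optimum that merges two
  planted themes; boundary recovery then degrades for that story.  Pooling
  across stories (as the study design does) makes aggregate properties
  robust to this; per-story results should be inspected via the written
  segmentation JSON.
- `select_num_events` over-segments under heavy window overlap; treat
  automatic E for stories as a starting point, not an inference.
- The block-permutation null is implemented as circular shifts (or full
  bin permutation); other block structures are possible and the published
  description does not pin one down.
- TextGrid parsing covers Praat's long and short text formats, not the
  binary format.
- The mixed model's story random effect is a variance component nested in
  the participant grouping, not a fully crossed intercept.
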
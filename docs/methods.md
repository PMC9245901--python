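# Methods

`neurostates` segments multi-neuron spike trains into discrete population
states and quantifies how those states correspond to behavior. This note
records the models, the numerical choices, and what the synthetic tests do
and do not demonstrate.

## Generative picture

The working assumption is that population activity switches between a
finite set of brain states: at each time bin the population is in one of
`K` discrete states `s_t` with Markovian dynamics; each state has a
stereotypical latent-factor vector `x_t`; firing rates `r_t` follow from
the latents through a linear readout; spike counts are Poisson given the
rates. The analysis inverts this picture in two stages — GPFA extracts
smooth latents from binned counts, a sticky Gaussian HMM segments the
latents — because the latent factors are Gaussian processes, so the HMM's
per-state observation model can be Gaussian.

## Preprocessing

* **Binning.** Spikes are counted in non-overlapping 250 ms bins, 0-based
  and half-open from the trial start; a trailing partial bin is dropped.
  Spikes between trials are retained in the data model but never analyzed.
* **Smoothing** (trial-averaged views only). Counts are convolved with a
  unit-sum Gaussian window with 500 ms half-width at half-maximum
  (σ = 0.5/√(2 ln 2) s ≈ 0.425 s; "half-width" is not otherwise defined,
  so HWHM is the package's reading, exposed as a parameter). The kernel is
  renormalized at trial edges so constant rates stay constant.
* **Normalization.** Per neuron, min-max scaling to [0, 1] across all
  concatenated bins of the trial set; a constant neuron maps to zeros.
* **Stretching.** Trials are aligned by mapping each trial's game-phase
  time points onto reference anchors (the per-phase medians across trials;
  across *all* sessions for cross-session analyses) with a
  piecewise-linear time warp. Continuous signals are resampled by linear
  interpolation, discrete labels by nearest original time with ties toward
  the earlier bin. Non-monotone median anchors (possible with few trials)
  are isotonically corrected and strictified by 1 µs.

## Latent dimensionality and GPFA

The number of latent factors per session uses a two-step rule: (1) factor
analysis models of increasing dimensionality are compared by 5-fold
cross-validated log-likelihood on the pooled binned counts; (2) the final
dimensionality is the smallest number of leading eigenvalues of the
winning model's shared covariance `CᵀC` reaching 95% of its trace. (`CᵀC`
and the more familiar `C Cᵀ` share their nonzero spectrum, so the 95% rule
is indifferent to the convention.) A session with no shared variance
floors at one dimension.

GPFA models binned counts as `y_t = C x_t + d + ε`, `ε ~ N(0, R)` with
diagonal `R`, and each latent as a stationary GP over the bin grid with a
squared-exponential kernel: signal variance `1 − σ_n²`, fixed noise floor
`σ_n² = 10⁻³`, one timescale `τ_i` per latent (initialized at 0.5 s,
bounded in [0.05, 10] s). Counts enter untransformed (a square-root
transform flag is deliberately absent: the analysis this package
reimplements feeds raw counts). EM details:

* E-step: exact Gaussian conditioning over all latents and bins of a
  trial at once (a `dT × dT` solve); trials of equal length share the
  posterior covariance.
* M-step: closed-form joint update of `C`, `d`, `R` (R floored at 10⁻⁶);
  each `τ_i` by bounded golden-section search on its expected complete
  log-likelihood, run every third iteration because it is the single most
  expensive step and converges on a slower timescale; a candidate τ is
  only accepted if it does not decrease the objective.
* Stopping: relative log-likelihood change below 10⁻⁶ or the iteration
  cap (default 50). The log-likelihood history is retained and is
  non-decreasing up to numerical tolerance.

Initialization is plain factor analysis on the pooled bins. Trials with
fewer than two bins are skipped.

## Sticky Gaussian HMM

Hidden states follow a Markov chain with initial distribution π₀ and
transition matrix A; emissions are full-covariance Gaussians over the
GPFA latents. Transition rows carry a sticky Dirichlet prior —
concentration α = 1 on every entry plus κ = 100 extra on the diagonal —
so the MAP M-step for row i is proportional to
`E[n_ij] + α − 1 + κ·δ_ij`, floored at 10⁻⁸ before normalization.
Covariances get a 10⁻⁶ ridge (escalated if a Cholesky fails). The MAP
objective (data log-likelihood + transition log-prior, additive constant
dropped) is non-decreasing across EM iterations.

Fitting restarts 40 times (restart r seeds K-means initialization with
`base_seed + r`: K-means centers for means, within-cluster covariances,
sticky-uniform A, uniform π₀) and keeps the highest final MAP objective.
All trials of a session are independent sequences under one model; the
forward-backward recursions are batched across trials. Segmentations are
decoded by Viterbi (ties toward the lower state index); probability
timecourses use the forward-backward posteriors γ.

The number of states K defaults to 11 for play-style sessions and 18 for
sessions that include observing trials; when a candidate list is given, K
is chosen by 10-fold cross-validation over whole trials, scoring each
fold's held-out log-likelihood normalized by its bin count. Held-out
likelihood keeps creeping upward with K when the within-state noise is
temporally correlated (extra states absorb slow drift), so CV recovers
the true K only when the emission model is approximately well-specified —
see the calibration comments below.

## Correspondence statistics

The HMM labeling and the tag-derived behavioral labeling are two
clusterings of the same bins; their similarity is the plug-in mutual
information in nats. The behavioral labeling assigns each bin the most
recent phase point's label, with tagged behavior intervals (darting etc.)
overriding phase labels where they overlap (precedence configurable).

* **Segment-shuffle null** (primary): per trial, permute the order of the
  run-length segments of the HMM labeling — labels and lengths preserved —
  concatenate across trials, recompute MI; 10,000 draws by default.
  p = (#null ≥ observed)/n, serialized as the bound 1/n with a
  `below_resolution` flag when the count is zero; an optional
  (k+1)/(n+1) estimator exists but the k/n convention is the default.
* **Cyclic-rotation null**: MI at every nonzero rotation of the
  concatenated HMM labels (null size = total bins − 1); preserves segment
  lengths *and* transition statistics.
* **Conditional probabilities**: row-stochastic P(behavior|state) and
  P(state|behavior) from joint counts; cell-wise p-values against the
  same segment-shuffle ensemble (same seed ⇒ identical draws); cells with
  observed probability ≤ 0.001 are excluded; Holm–Bonferroni at α = 0.05
  across all included cells of both matrices jointly.
* **Role separation** (playing vs observing): P(observing|state) per
  state; the *mixing fraction* is the share of total time in states with
  0.3 < P(observing|state) < 0.7; the state-vs-role MI is tested against
  a segment-relabel null (boundaries kept, each segment's label redrawn
  uniformly from the K states).
* **Event timecourses**: per-state γ averaged across all tagged events of
  a behavior, each window (event ± 1 s pad) warped onto a common grid
  whose anchors are window start, event start, event end (event body
  stretched to the median event duration), window end.

## Cross-session state matching

Each session gets its own HMM, so state labels are arbitrary per session.
For every role, each state's trial-averaged stretched γ timecourse is
computed on global anchors (medians over every trial of every session);
states of two sessions are paired by the Hungarian algorithm on the
negative mean of the per-role Pearson correlation matrices. Correlation is
scale-invariant, so the timecourses enter raw. A constant timecourse has
undefined correlation and is assigned 0. Among equally optimal
assignments the lexicographically smallest is returned (rows fixed
greedily, each candidate verified by re-solving the remainder). The
reference session maximizes the mean matched total correlation over all
partners (ties → session order); other sessions are relabeled by their
assignment to it. Cosine similarity is available behind a flag.

## Decoding check

A random forest (scikit-learn defaults, recorded in the report) predicts
the per-bin behavioral label from the GPFA factors, 10-fold
cross-validated by whole trials. It is compared with "stratified" and
"most frequent" dummy classifiers by one-sided Wilcoxon signed-rank tests
across folds (zero differences dropped; an all-zero-difference test
reports p = 1 by convention); the reported p is the larger of the two.

## Synthetic sessions

The generator emulates a recorded session under the generative picture
above, with defaults chosen as a realistic well-powered session: 8 latent
states, 20 neurons, 15 trials per role (hide and seek), ~60 s trials,
250 ms bins, latent dimension 3, GP wander with 0.4 s timescale and 0.25
sd (in latent units; the amplitude is a package parameter, since only the
kernel family is implied by the model), softplus rate link (keeps rates
positive, near-linear when high; the link is otherwise unconstrained),
baselines drawn so that baseline rates span roughly 2–10 spikes/s.

Trial structure is dwell-driven: each game-phase segment (and optional
free-state insertions such as "darting", probability 0.25 per phase)
draws a geometric dwell with mean `stickiness` bins, so the empirical
self-transition rate is 1 − 1/stickiness and the mean trial duration
emerges from the dwell process; by default `stickiness` is derived from
the target mean trial duration. When an exact bin count is requested the
dwells are rescaled proportionally.

Human-style tags are imperfect observations of the truth: phase points
get N(0, 0.5² s) jitter (clipped to the trial, order-preserving); each
behavior interval is independently mislabeled with probability 0.05.
These two defaults are the package's own choice of a plausible
human-tagging noise level — no quantitative tagging-noise model exists to
copy — and are exposed in the config.

**What the generator does not emulate:** non-Poisson spiking (bursting,
refractoriness), rate nonstationarity across a session, neuron loss or
drift, correlated tagging errors, inter-trial activity, or any real
relation between video-taggable behavior and neural state beyond the
shared latent chain. Passing tests therefore show the *pipeline* is
correct and calibrated under its own assumptions, not that real cortical
data satisfy them.

**Recovery-test regime.** For parameter-recovery and model-selection
checks the generator is run with the GP wander timescale below the bin
width (0.1 s vs 0.25 s), which makes the within-state noise effectively
white and the HMM emission model well-specified; with correlated wander,
cross-validated likelihood genuinely favors extra states that soak up
slow drift, which is a property of the method (and the reason K selection
on real data is treated as a guide, not ground truth), not a bug.

## Problem sizes and determinism

The test suite runs every stage at deliberately reduced sizes (about
5–15 trials of 25–40 s, 10–14 neurons, 2–8 HMM restarts, nulls of
300–10,000 draws) chosen to exercise the same code paths the full-scale
script uses. `scripts/acceptance.py` runs the headline computation at
full scale (30 trials, 20 neurons, K = 11, 40 restarts, 10,000 shuffles).
All randomness flows from explicit seeds: the generator from
`(config, seed)`, HMM restarts from `base_seed + restart`, every null
and fold split from a stage seed recorded in the report; re-running a
pipeline with the same config and seed reproduces the report bit for bit.

## Known limitations

* GPFA's E-step is an exact dense solve, O((d·T)³) per trial; sessions
  with trials much longer than a few hundred bins would need a banded or
  low-rank approximation.
* The MI p-value convention k/n is conservative at 0 and reported as a
  bound; the (k+1)/(n+1) estimator is available.
* Cross-validated K selection drifts upward under model mismatch (see
  above); the package reports the full per-K table so users can apply
  their own parsimony rule.
* Failed trials are carried as a flag but never modeled.
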
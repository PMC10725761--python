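# Methods

This note documents the models implemented in `chordexpect`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions inside the sampler and evaluators.

## Chord representation

Chords are reduced to a root pitch class (0–11, C = 0) × nine quality
classes (maj, min, dom7, maj7, min7, dim, aug, sus, other), serialized as
Harte-style `root:quality` tokens. Raw Harte annotations carry a far richer
grammar (inversions, added notes); the reduction bounds the symbolic
vocabulary at 108 tokens so n-gram counts stay dense at desk scale. The
mapping from raw qualities is a fixed table (`HARTE_QUALITY_MAP`);
syntactically valid but unrecognized qualities fall into `other`, and
no-chord (`N`) events are dropped before modelling. Sequences are transposed
so the annotated key maps to C. Symbolic-to-acoustic rendering uses a
deterministic root-position closed voicing anchored at MIDI octave 4
(C4 = 60); the voicing is a package convention, exposed via
`VoicingPolicy`, because symbolic chord labels do not determine a pitch set.

## Symbolic expectancy (PPM)

The long-term model counts (context, continuation) pairs for all orders
0..10 over a training corpus; the short-term model does the same over the
current song's prefix with unbounded order (order = prefix length, the
literal reading of "unbounded"). Prediction uses interpolated escape
smoothing, escape method C, without update exclusion:

    p(s | ctx) = c(ctx, s) / (n + t) + t / (n + t) * p(s | ctx[1:])

where `n` is the context's total count and `t` its number of distinct
continuations, bottoming out at the uniform distribution over the training
vocabulary (this order-(−1) floor guarantees strictly positive
probabilities, hence finite IC). The recursion starts at the longest
observed suffix of the context. Method C was chosen as the reference
configuration because it is simple, standard and easy to oracle-test; the
escape method is exposed in `SymbolicConfig`. The exact escape/exclusion
configuration of historical variable-order implementations varies, so the
reference configuration is a declared choice, not a reconstruction.

LTM and STM distributions are combined by an element-wise geometric mean and
renormalized (IC and entropy require a proper distribution). Cross-validated
corpus scoring partitions songs into 10 folds by a seeded shuffle; each
song's LTM excludes its own fold. Tokens present in a held-out song but
absent from the training vocabulary are added with a warning (uniform-floor
mass keeps their IC finite). A bigram variant caps both components at a
single-chord context.

Consistency: on data from a known first-order Markov chain the held-out IC
of the corpus-trained component converges to the chain's conditional entropy
rate (within ~2% at 10⁴ training events in the test suite). The *combined*
LTM+STM surprise does not converge to the rate at 30–38-chord song lengths:
the STM is refit within every song, so its finite-sample overhead is
irreducible by corpus size. Tests check both facts.

## Sensory expectancy

**Spectral distance.** Each chord tone contributes 12 harmonic partials with
weight i^−0.75 on a circular log-frequency axis of 1200 bins/octave (1 bin =
1 cent), folded to pitch class, with partials rounded to the nearest bin.
The smoothing parameter 6.83 is interpreted as the Gaussian σ in bins
(cents) on this axis; smoothing is circular and mass-preserving. SD between
adjacent chords is the cosine distance of their smoothed spectra (0 =
parallel, 1 = orthogonal). This reproduces the expected tonal-hierarchy
ordering, e.g. SD(C:maj, G:maj) < SD(C:maj, F#:maj).

**Periodicity pitch.** The original model front end transduces audio through
a cochlear/inner-hair-cell simulation followed by windowed autocorrelation.
That stage is deliberately replaced here by an idealized periodicity image:
subharmonic summation over the smoothed harmonic spectrum (evidence for
periodicity bin b = Σ_m decay^(m−1) · spectrum at b's m-th harmonic bin,
m ≤ 12, decay 0.84 — the classic subharmonic-summation attenuation). This
keeps the part of the model that carries its explanatory claims — the dual
leaky-integrated memory images and their correlation — while being
deterministic and audio-free. Consequences: absolute tonal-dissimilarity
values are not comparable to the audio-based implementation, and timbre
effects are outside the model; the within-stimulus *profile* (what enters
the regressions after standardization) is what the approximation preserves.

Memory update per chord over its 2.4 s duration:
`image ← e^(−Δt/τ)·image + (1 − e^(−Δt/τ))·instantaneous`. The decay grid is
τ_global ∈ {1.5, 2.5, 4.0} s × τ_local ∈ {0.1, 0.5} s with (4.0, 0.5) the
default selected pair. Tonal dissimilarity is −arctanh(r) of the Pearson
correlation between the global image at the *end of the previous chord*
(strict preceding context; the alternative including the current chord is
available behind a flag) and the local image after the current chord; r is
clamped to ±(1 − 10⁻⁶) so identical images give a large finite negative
value. The first chord of a sequence has no context and emits NaN; those
rows leave the analysis with the first-chord discard.

## Behavioural preprocessing

Slider traces are 20 Hz integer streams in [0, 1023]. The five-sample
symmetric median filter uses shrunken symmetric windows at the edges (no
padding artefacts). The per-chord rating is the mode of the filtered values
in [onset + 1 s, next onset) — the 1 s offset absorbs reaction delay — with
ties broken toward the smallest value (any deterministic rule works; this
one is stable under order-preserving relabelling). First-chord ratings are
discarded (the slider starts reset), remaining ratings are averaged within
group, and all modelled variables are standardized (recorded means/sds
support the inverse map). Row-count identity: rows = (Σ song lengths −
number of songs) × number of groups. Stationarity is assessed per series
with an ADF test (drift term, AIC-selected lag ≤ 10, 5% level); following
the analysis this mirrors, differencing is not applied — the check is
computed and reported only.

## Multilevel AR(1) regression

One observation per (song, position, group) in Experiment-1-style data.
Every slope term appears both as a population-level coefficient and as a
song-level varying effect (standard hierarchical centering); reported
effects are the population-level means, and group-specific slopes are
draw-wise contrasts β_pred + β_pred×musicianship · (group code). Musicianship
is the standardized binary group code (±1 with equal groups). Preset term
lists: the null model has musicianship, valence, arousal; single-predictor
models add the predictor and its musicianship interaction; the additive
model includes both IC and tonal dissimilarity terms; the supra-additive
model adds their product terms. Experiment-2-style presets carry valence,
arousal, dissonance, spectral centroid and spectral complexity as
covariates, with IC, entropy, IC×entropy and/or tonal dissimilarity as
predictors.

Likelihood: Gaussian with stationary AR(1) residuals along chord order
within each song × group series (one shared ρ); the first observation of a
series uses the marginal variance σ²/(1−ρ²). Priors: Normal(0,1) on
coefficients, Half-Cauchy(0,1) on all scales (song-effect τ's and σ), LKJ(2)
on the song-effect correlation matrix, Uniform(−1,1) on ρ (unstated
elsewhere; uninformative and stationary).

**Sampler.** No general-purpose MCMC framework is a dependency; the model
family is narrow enough that a dedicated blocked sampler is both faster and
exactly tailored:

- β and each b_s have Gaussian full conditionals after AR(1) whitening
  (y*_t = y_t − ρ y_{t−1}; first-of-series rows scaled by √(1−ρ²)), drawn
  exactly per sweep.
- (τ, C) are updated by per-coordinate adaptive random-walk Metropolis on
  log τ and the unconstrained canonical partial correlations (CPCs) of C.
  Under the C-vine CPC parameterization, LKJ(η) factorizes into independent
  scaled Beta(a_j, a_j) laws with a_j = η + (q − 2 − j)/2 for CPC column j;
  this correspondence is verified in the test suite against the known LKJ
  marginal-correlation law.
- The centered conditional of τ given b collapses near τ = 0 (the funnel),
  so each sweep adds an interweaved ancillary move: holding the
  standardized effects u = (diag(τ)L)⁻¹ b fixed, each τ_j is re-updated
  against the whitened data likelihood. This is an exact
  Metropolis-within-Gibbs move and restores mixing of the scale parameters.
- (ρ, σ) are updated by adaptive Metropolis on (atanh ρ, log σ) against the
  exact AR(1) residual likelihood.

Proposal scales adapt toward 0.44 acceptance during warm-up only. The
default budget is 4 chains × 2500 warm-up + 2500 kept draws; tests and the
acceptance script use scaled-down budgets (2 chains × a few hundred sweeps),
which the convergence diagnostics reflect — split R-hat and bulk ESS are
computed for every reported parameter and a `ConvergenceWarning` is raised
when max R-hat ≥ 1.01. Posterior summaries are means with central 95%
credible intervals (2.5–97.5 percentiles).

**Pointwise likelihood and model comparison.** The pointwise log-likelihood
for PSIS-LOO uses the AR(1) innovation decomposition (each observation
conditioned on its predecessor in the series; series starts use the
stationary marginal). This is the natural pointwise factorization for an
autoregressive likelihood, but it is a convention: ELPD magnitudes are
comparable between models fitted here, not across implementations with a
different factorization. PSIS smoothing (generalized-Pareto fit to the top
20% of importance ratios, truncation) is delegated to `arviz.psislw`;
observations with Pareto k > 0.7 are flagged. dSE uses the paired pointwise
differences. Stacking maximizes Σ_n log Σ_k w_k p_k(y_n) over the simplex
by SLSQP from the uniform start; the objective is concave, so the solution
is unique up to ties, and exact ties return uniform weights.

## Synthetic data: what it emulates, what it does not

The generator mirrors the statistical structure the analysis assumes:

- *Corpus/stimuli*: a first-order Markov chain over chord tokens with
  Dirichlet(0.1)-drawn sparse rows (vocabulary 24, corpus 120 songs by
  default). Sparse rows make most transitions predictable and a few
  surprising, reproducing the left-dominated IC density with a heavy right
  tail; as the concentration grows the chain tends to uniform and the skew
  vanishes. First order keeps brute-force oracles tractable while still
  exercising the variable-order blending. Stimuli are 30 progressions of
  30–38 chords (optionally constrained to exactly 1039 chords, the stimulus
  total this design emulates) at 2.4 s per chord.
- *Raters*: latent rating = population betas × standardized predictors +
  song-level Gaussian effects (scale 0.1) + per-subject stationary AR(1)
  chains (ρ = 0.3, subject-level innovation sd 2.5, so the 13/12-subject
  group averages have innovation sd ≈ 0.71 and total variance near 1 on the
  standardized scale). Default betas are the reported posterior means of the
  additive analysis (IC 0.519/0.305 by group, tonal dissimilarity
  0.188/0.170, musician shift −0.280, arousal 0.177, valence 0.029) —
  simulation inputs chosen to exercise realistic signal-to-noise, not
  reproduction claims.
- *Sliders*: piecewise-constant traces at 20 Hz starting at 0, jumping to
  each chord's affine-mapped target (centre 512, gain 180) after a 1.0 s
  reaction delay, with small per-sample jitter (sd 2). The preprocessing
  uses only within-window order statistics, so richer slider kinematics
  would not change what the pipeline extracts; with zero jitter the
  pipeline recovers the discretized latents exactly.

Not emulated: audio (timbre, rhythm tracks), familiarity and closure
effects, non-stationary drifts in slider use, subject-level heterogeneity in
effect sizes, and any dependence of valence/arousal on the music (they are
independent per-song covariates here). Passing tests therefore demonstrate
that the pipeline recovers the structure it assumes — they do not validate
the cognitive claims on real listeners.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep the whole suite
in minutes on one CPU: corpora of 50–120 songs, the full 30-stimulus / 1039
chord design for pipeline-level checks, 2 chains × 250–400 kept draws for
smoke fits, 5-replicate recovery suites. Deterministic seeding covers every
random stage (corpus, folds, raters, sampler chains, posterior-predictive
draws). Tie-breaks and degenerate-input policies are explicit: smallest
value wins rating-mode ties; zero-variance inputs to standardization, ADF or
image correlation raise data errors; correlations are clamped before
Fisher-z; harmonic partials round to the nearest cent bin.

## Known limitations

- The PP front end is an idealized stand-in (see above); SD and PP share the
  same spectral representation, which likely overstates their similarity
  relative to audio-based implementations.
- The PPM configuration is one member of the escape-method family; IC values
  shift by fractions of a bit across members (orderings are stable in our
  tests).
- The sampler is exact but not gradient-based; very small effective sample
  sizes can occur for scale parameters whose posteriors concentrate near
  zero. Diagnostics are always attached; raise the budget when R-hat warns.
- ELPD magnitudes depend on the AR(1) pointwise factorization convention and
  on the synthetic study's signal-to-noise; orderings, not magnitudes, are
  the meaningful output.
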
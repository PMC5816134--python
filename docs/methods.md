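# Methods

`vocalrep` implements a complete analysis chain for perceptual
categorization of human non-linguistic vocalizations (laughs, cries,
screams, moans, …): naming-based semantic spaces, acoustic–semantic
alignment, hierarchical models of naming behavior, and a Bayesian embedding
of triad similarity judgments.  Every stage is exercised against a
synthetic-data generator with known ground truth, so recovery properties
can be tested end to end.

## The synthetic study

`synthdata.make_world` draws a Gaussian-mixture configuration of call types
in a low-dimensional latent perceptual space.  Defaults match the scale of
the kind of study the package targets: **132 stimuli**, **6 call types**
(laugh, cry, scream, moan, sigh, roar), **3 latent dimensions**, type
centers rejection-sampled with pairwise separation ≥ 4 (arbitrary latent
units), within-type spread 1.  Laugh and cry are *compact* types (spread/5):
the repertoire has two tight clusters and a graded remainder.  Each
stimulus also carries one of nine contextual-emotional categories
(amusement, anger, disgust, effort, fear, joy, pain, pleasure, sadness)
sampled from a type-specific distribution.

**Naming model.** Each language's lexicon places one prototype point per
label near its call type's center (sound labels: jitter sd 0.8; emotion
labels: jitter sd 0.4, so several emotion labels crowd each center).  A
trial's label-choice probabilities are a softmax over negative
stimulus–prototype distances with temperature 1.6 for sound names and
1.6 × 1.7 for emotion names.  Any additional label whose probability clears
0.25 is also chosen (multi-label responses).  These four numbers were fixed
once so that the simulated study reproduces the qualitative asymmetry such
experiments report — emotion naming less consistent (normalized entropy
roughly 40–45% for sound vs 50–55% for emotion names) and less certain than
sound naming — and are not tuned per analysis.  The confusion model itself
is a modeling choice: real naming data constrain only the observed label
distributions, not the mechanism.

**Certainty** is ordinal: latent = 7 × (distance margin between the best
and second-best prototype) + logistic noise, cut at (0.0, 1.8) into Don't
know / Unsure / Sure.  **Latencies** are lognormal with crossed participant
(sd 0.3) and stimulus (sd 0.2) random intercepts, residual sd 0.4, location
log 5 s for the first sound name, +0.2 log-units for the first emotion
name, and a ±0.25 log-unit advantage for whichever response block sits on
the left of the (counterbalanced) screen layout.  Response *order* is a
by-product of the two latencies, so the sound-first preference and the
reading-order effect fall out of one mechanism rather than a second,
possibly inconsistent process.  `simulate_order_trials` additionally
exposes a direct logistic order generator for calibration tests of the
order model alone.

**Acoustics.** Features are noisy linear images of the latent coordinates
(loadings drawn once per seed unless supplied), with Gaussian noise sd 0.5
and 4 pure-noise distractor columns among the 12 conventionally named
features (amplitude median, proportion voiced, pitch median/SD, spectral
first-quartile median/SD, spectral-entropy SD, interburst-interval
median/SD, number of bursts, syllable-length median/SD).  **Triad choices**
follow the same softmax law the inference model assumes (below),
temperature 1.

What the generator does *not* emulate: acoustic nonlinearities and
within-call structure, participant-level response styles beyond a random
intercept, dropout/attention artifacts, or cross-language differences
beyond separate lexicons.  Passing recovery tests therefore demonstrates
the *statistical machinery* is correct and well calibrated, not that real
naming data satisfy the generator's assumptions.

## Semantic spaces

Per-stimulus label-choice **profiles** (proportions over the label list;
multi-label trials contribute one count per chosen label) give pairwise
Euclidean **co-occurrence distances**: two stimuli are close when they
attract the same names.  Whether to compute these on counts or proportions,
pooled or per participant, is a genuine design opening; we use pooled
proportions, which makes the distances invariant to duplicating trials.
Per-language matrices are averaged elementwise across languages.

**Embedding** is classical (Torgerson) MDS — eigendecomposition of the
double-centered squared-distance matrix — exact on Euclidean input;
PCA on centered profiles is available as an alternative and coincides with
MDS for Euclidean profile distances.  Explained variance is reported as
eigenvalue shares among the nonnegative eigenvalues.

**Clustering** is affinity propagation on similarities s = −d², with every
self-similarity set to the q-quantile of the off-diagonal similarities.
The preference quantile q tunes splitting (high q) versus lumping (low q)
and is swept over a grid; solutions are scored by mean silhouette and by
the adjusted Rand index against the partition induced by each stimulus's
modal name.  Message passing uses damping 0.9, max 1000 iterations, and
declares convergence after 50 iterations of a stable exemplar set;
non-convergence is always reported, never silent.  After message passing,
the exemplar set is finalized: instances small enough to enumerate
(n ≤ 12) get the exactly optimal exemplar set by exhaustive search over
subsets, and larger instances a greedy add/remove/swap local search on the
net-similarity objective from two starts (the message-passing solution and
the best single medoid).  Damped message passing occasionally converges to
a suboptimal fixed point on tiny instances; the exact finalization removes
this entirely where it is cheap, and the local search removes most of it
elsewhere.

**Prototypicality-adjusted centroids** weight each cluster member by
(mean rater certainty) × (modal-name proportion); **cladograms** are
average-linkage trees, exportable as Newick.

Modal-label ties break to the lowest-index label in the label-list order
and are flagged.  Silhouette follows the standard conventions: singletons
score 0, and a = b = 0 (identical points) scores 0.

## Naming statistics

**Normalized entropy** of the names given to a stimulus is Shannon entropy
of the choice counts divided by log₂(number of alternative labels), as a
percentage; 0% means perfect agreement, 100% a uniform spread over all
labels.  The sound-vs-emotion consistency contrast is a Bayesian Gaussian
model on paired per-stimulus differences (noninformative
normal–inverse-χ² posterior), reporting the mean difference, 95% interval
and Cohen's d.

**Response times** (first click per block, log scale, responses over 60 s
removed as attention lapses) follow a Gaussian model with fixed effects for
name kind (emotion vs sound, ±½ coding) and screen side (right vs left)
and crossed random intercepts for participant and stimulus.  This model is
fully conjugate, so it is fit by an exact Gibbs sampler (default 1500
iterations, 500 warmup): normal(0, 2.5²) priors on fixed effects and
weakly-informative inverse-gamma(2, 0.5) priors on the three variance
components.  The inverse-gamma replaces a half-normal prior on the sd scale
purely for conjugacy; both are weak at these data sizes.  A back-transformed
millisecond contrast at the mean intercept is reported alongside the
log-scale effect.

**Certainty** uses a cumulative-logit model with the same two random
intercepts, and **response order** (did the participant name the sound
first?) a logistic model with a participant intercept and a layout
covariate.  Both are fit by blocked Metropolis-within-Gibbs: a joint
random-walk update for the global parameters and vectorized per-group
accept/reject sweeps for the random-effect vectors (valid because the
likelihood factorizes over groups), with step sizes adapted during warmup
only.  Priors: normal(0, 2.5) on global parameters, half-normal(0, 1) on
random-effect sds.  The **preference odds ratio** is defined under
symmetric ±½ layout coding as exp(preference): the odds of starting with
the sound block when it is on the right, relative to the odds of starting
with the emotion block when it is on the right — i.e. the tendency to cross
the reading order in favor of sound naming, net of layout.

The **sound-name × emotion-name contingency table** counts one entry per
chosen label pair per trial; independence is tested by Pearson chi-square
without continuity correction, and rows/columns can be ordered by
average-linkage clustering of their profiles for display.  A random forest
(500 trees, stratified cross-validation) predicts the primary emotion name
from multi-hot sound-name features; fold counts shrink with a warning when
a class is rarer than the fold count.

## Acoustic alignment

Features are z-scored (population sd) so learned weights are comparable.
The acoustic space is a weighted Euclidean metric; weights ≥ 0 are learned
by maximizing the Mantel-style Pearson correlation between the weighted
acoustic distances and a reference (semantic) distance matrix, computed
over strict upper triangles.  The optimizer is multi-start Nelder-Mead on
log-weights followed by greedy exact-zero drop moves with re-polish — so
feature-subset selection and weighting are one mechanism — and never
returns a solution below the uniform-weights baseline (returned with a
warning flag if optimization fails to improve).  Recovered weights are
normalized to mean 1 over the selected features; the objective is
scale-free.  PCA of the weighted table (SVD, loading signs fixed so each
column's largest-magnitude entry is positive) summarizes the space; a
multinomial logistic model on the first two PCs (ridge 10⁻⁴ for
separability) draws decision regions; and a random forest classifies call
types from the 12 features, either at full label granularity or pooled to
the six major types plus "other".

## Triad embedding

Each stimulus is a point in d dimensions.  For a triad {i, j, k} the
probability of judging a pair most similar is
P(pair) ∝ exp(−d_pair / τ) — the closest pair is the most likely choice.
The softmax-over-negative-distances link with τ = 1 is the minimal monotone
choice law; the distance scale is then identified by the data and the
normal(0, prior_sd = 1) coordinate priors.  Sampling is Hamiltonian Monte
Carlo with analytic gradients, jittered leapfrog trajectories (15 ± 20%
steps) and dual-averaging step-size adaptation toward 80% acceptance
(defaults: 4 chains × 500 warmup + 500 samples; any participant with ≥ 1
triad contributes, with a configurable inclusion threshold).

The likelihood is invariant under global rotations, reflections and
translations, so no identifiability constraints are imposed; every reported
summary is distance-based.  In particular the posterior distance matrix is
the **posterior mean of per-draw pairwise distances** — not the distances
of posterior-mean coordinates, which shrink toward zero as chains explore
different orientations.  Convergence is monitored on isometry-invariant
summaries (total log likelihood, a reference interpoint distance) via ESS
and R-hat; a failing R-hat sets a diagnostics flag, never silently.

Dimensionality is compared by **WAIC** from the stored pointwise log
likelihoods: lppd − p_waic with p_waic the per-trial posterior variance of
the log likelihood (population variance, which is exactly invariant to
duplicating draws and matches arviz), reported on the deviance scale.
Procrustes alignment (translation + rotation/reflection + uniform scaling)
is provided for visual comparison of configurations only.

## Numerical choices and degenerate inputs

- Distance matrices are validated (symmetry 1e-8, nonnegativity, zero
  diagonal) and symmetrized on construction.
- MDS truncates with a warning when fewer nonnegative eigenvalues exist
  than requested components; PCA truncates at numerical rank.
- Softmax computations subtract the row minimum before exponentiation, so
  temperature → 0 limits are exact argmax/argmin without overflow.
- Zero-variance paired differences give a point-mass posterior (d = 0).
- Identical-point distance matrices make affinity propagation oscillate;
  the solution is returned with `converged=False`.

## Problem sizes used in tests

Recovery suites run at the documented study scale where the property
demands it (132 stimuli × 50 participants for the response-time recovery;
30 stimuli, 150 × 42 triads for triad distance recovery) and at reduced
replicate counts/sampler settings for calibration sweeps (40 null
replicates at 60 stimuli × 25 participants; 10 WAIC model-selection
replicates at 20 stimuli).  These sizes are chosen to make Monte-Carlo
error small relative to the tested tolerances.

## Known limitations

- The naming confusion, certainty and latency mechanisms are synthetic
  stand-ins; only their statistical *form* mirrors the analyses' assumptions.
- The MH sampler for ordinal/logistic models is serviceable at these data
  sizes but mixes more slowly than gradient-based samplers; ESS diagnostics
  are attached to every fit.
- WAIC comparisons between embedding dimensions ignore posterior
  multimodality across isometry classes (harmless for distance summaries).
- Affinity propagation's preference-quantile sweep reports all solutions;
  choosing "the" repertoire size from several valid clustering solutions
  remains a judgment call, as it is in practice.
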
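# Methods

This note documents the models, numerical choices and limitations behind
`pawbias`. It covers what each component assumes, which knobs matter, what
the synthetic generators do and do not emulate, and where the design was
genuinely open.

## Laterality scoring

A session is an ordered sequence of left/right paw responses for one
subject × test (food-reaching FRT or Kong KT) × condition (baseline or
open-field OFT), nominally 50 responses. Scoring is closed-form:

- `LI = (R − L)/(R + L)`, direction of preference in [−1, +1];
- `|LI|`, strength of preference, independent of direction;
- `z = (R − 0.5 N)/√(0.25 N)`, the normal approximation to the binomial
  test of `R` against fairness.

Classification uses inclusive boundaries: right-pawed iff `z ≥ 1.96`,
left-pawed iff `z ≤ −1.96`, ambilateral strictly between. At `N = 50`
this is equivalent to `R ≥ 32` (right) and `R ≤ 18` (left); the test
suite verifies the equivalence by brute force. The normal approximation
is the field's convention for this assay; it is slightly anticonservative
relative to an exact binomial criterion at `N = 50` (the exact two-sided
p at `R = 32` is 0.065), which matters when comparing ambilateral
fractions to studies using exact per-dog tests.

Sessions shorter than the 50-response target are scored but flagged
`complete=False`; all cohort-level analyses drop flagged sessions by
default (configurable), since non-completers are not comparable on the
same binomial footing.

### Distribution test

Preference-class counts per test × condition are tested against an equal
null proportion of 1/3 with an exact two-sided binomial test using the
"small p-values" method: the p-value sums the probabilities of all
outcomes whose point probability does not exceed the observed outcome's
(scipy's `binomtest`). A count exactly at the null expectation yields
p = 1. An independent brute-force pmf summation in the test suite agrees
to 1e−12. No multiple-testing correction is applied across the class ×
test × condition family (α = 0.05 per test); users comparing many strata
should correct accordingly.

### Zero-variance inputs

All t-family routines raise `DegenerateVarianceError` on zero-variance
input rather than returning 0/0 or ±inf. Pathological fixtures should
surface, not propagate silently.

## Mixed models

The study design is a split-plot: group (CS/EH) between subjects,
condition within subjects. Subjects missing any condition level are
dropped listwise before fitting (no imputation), which reproduces the
varying per-analysis n's typical of such studies.

`mixed_anova` (2 or 3 within levels, no covariate) delegates to
pingouin's split-plot implementation; effects are reported with partial
η². No sphericity correction is applied (with two levels sphericity is
trivial; at three levels the uncorrected F matches the reporting style
this pipeline mirrors).

`mixed_ancova` (exactly 2 within levels, binary/continuous subject-level
covariate) is fitted by the exact mean/difference decomposition of the
repeated-measures GLM: between-subject effects (group, covariate) are OLS
F-tests on per-subject condition means; the condition main effect, the
group × condition interaction and the condition × covariate term are OLS
F-tests on per-subject difference scores. The group factor is
effect-coded (±1/2) and the covariate centred, so every single-df test is
evaluated at the unweighted design centre — the Type III convention of
standard statistical packages. For two within-subject levels this
decomposition is algebraically identical to the full mixed-model fit, not
an approximation. Denominator df is `n − 3` throughout.

Calibration is verified rather than assumed: under a null interaction the
interaction p-values are uniform (KS test over 500 simulated datasets),
and permuting the covariate leaves null group-effect p-values uniform.

### Normality gate

Shapiro–Wilk at α = 0.05; on rejection the test is retried on
log-transformed values when all are positive; a second rejection (or
non-positive values) flags the nonparametric path (Mann–Whitney /
Wilcoxon). In the pipeline the gate's verdict is applied for the
log-transform case and logged otherwise; the default group comparisons
stay on the t/F path, with the rank-based fallback available explicitly.

## Trajectory analytics

Input is the markerless-pose CSV export dialect (three header rows:
scorer / bodyparts / coords; x, y, likelihood per bodypart per frame),
with at least `body` and `head` tracked. Coordinates are in image
convention: y increases downward.

**Cleaning.** Points below the likelihood threshold (default 0.9) are
replaced by linear interpolation from confident neighbours, then each
coordinate series is smoothed by a cubic smoothing spline. The
`smoothing` parameter is the tolerated mean squared residual per point in
px² (default 4.0, i.e. a ~2 px tracking-noise budget; 0 gives an
interpolating spline). A bodypart with more than 50% sub-threshold frames
raises an untrackable-video error. Both defaults are configuration-exposed
because tracking quality varies by setup.

**Speed.** Frame-to-frame Euclidean displacement of the body centroid,
in px/frame (m/s available when a pixels-per-metre scale is supplied).
Speeds are reported unitless by default; group contrasts are unaffected,
but absolute speeds are not comparable across camera setups without the
scale.

**State segmentation.** A 3-state Gaussian HMM on `log(speed + ε)`,
ε = 1e−6, fitted by EM with 5 restarts, best log-likelihood kept, Viterbi
decoding. The first restart is fully deterministic — emission means at
the 10th/50th/90th percentiles of the log-speed, uniform start and
transition probabilities, data-variance emissions — because k-means
initialisations can collectively land in a poor local optimum on
log-speed data with a heavy left tail; the remaining restarts are
k-means-seeded to probe other basins. States are relabelled by ascending
emission mean to resting / marginal / running, making the labelling
invariant to EM's arbitrary state order. Non-convergence raises an error
carrying the log-likelihood trace.

**Object proximity.** Mean body-to-object distance and the fraction of
frames within `near_threshold` (default: one median body length, the
head-to-body distance) over the object's active epoch only — by default
the final 60 s of a 5-minute recording, when the novel object is present.
Whether proximity should be epoch-only or whole-session is configurable;
epoch-only is the default since the object does not exist outside it.

**Turning events.** Orientation is the angle of the head-minus-body
vector; frame-to-frame differences are wrapped to (−180°, 180°]. The
detector accumulates consecutive same-sign differences; when the
magnitude exceeds 45° the turn is armed, and it is emitted — counted once,
which is the guard against double-counting turns beyond 90° — at the
first subsequent frame whose absolute difference falls below 2°. Three
rules complete the definition where it was open:

- a sign change resets an *unarmed* accumulator (a turn is directional;
  opposite motion before 45° cancels the pending accumulation and
  prevents alternating jitter from summing into a spurious turn);
- while *armed*, all differences keep accruing until closure;
- a turn still armed at the end of the recording is emitted there, so a
  final sustained turn is not lost.

Sign convention: in image coordinates (y down) a positive wrapped
difference is a clockwise turn on screen, which with an overhead camera
is the subject's **left** turn. The convention is arbitrary but fixed,
and the mirror-equivariance tests (reflecting x swaps left/right counts
exactly) pin it. Frames where head and body coincide carry the previous
orientation forward with a logged warning.

`turning_bias` is the proportion of left events; with no events it is
reported as missing (NaN), never as 0. The approach-phase bias restricts
to events starting inside the object epoch whose net body-to-object
distance change is negative ("approaching" was undefined; a negative
distance trend over the event is the implementation's definition).

## Synthetic generators

The paw-event generator draws each dog's right-paw probability θ from a
symmetric Beta(a, a): the concentration `a` is the single interpretable
knob, mapped numerically to the expected strength `E|2θ − 1|` (defaults
tuned to mean |LI| 0.35 for CS and 0.53 for EH dogs, the study-sized
group gap). Each dog's latent θ is shared across conditions, then
per-condition jitter (sd 0.05) is added and the OFT-condition θ is shrunk
toward 0.5 by the `acute_shift` factor (default 0.25) — reproducing both
the baseline↔OFT consistency of preferences and the acute shift toward
ambilaterality. Trials are Bernoulli(θ), 50 per completed session;
completion rates default to the study's (≈78% FRT, ≈63% KT), with
non-completers receiving 25–49 trials. At `acute_shift = 1` every OFT θ
is exactly 0.5 and the expected ambilateral fraction equals the binomial
mass of 19 ≤ R ≤ 31 at N = 50 (≈0.935), which the tests verify.

The trajectory generator simulates a sticky 3-state Markov chain
(stay-probability 0.95) whose states emit speeds |N(μ, σ)| with defaults
μ = 0.2/2/8 px/frame, σ = 0.1 (well-separated regimes at 30 fps);
heading accrues small Gaussian jitter (sd 0.5°/frame) between injected
turning episodes — same-sign increments of 5–15° per frame until a
60–120° target is passed, closed by a sub-1° frame — whose direction is
Bernoulli(left-turn probability). Positions integrate speed along the
heading; head sits one body length (40 px) ahead of the body. Gaussian
tracking noise (default sd 1 px) and likelihood dropouts (default 2%,
likelihood < 0.5 with 50 px coordinate corruption) are applied last.
Ground truth (state path, injected events) is always returned.

What the generators do **not** emulate: arena walls (the walk is
unbounded), body articulation beyond a rigid head-body axis,
autocorrelated tracking error, per-breed or per-age heterogeneity in
preference, and any physiological coupling (cortisol/heart/respiratory
values are drawn from configured normal distributions around the study's
condition means, uncorrelated with behavior). Passing recovery tests
therefore demonstrates the estimators' correctness under the stated
generative model, not robustness to every property of real videos. One
visible consequence: with tracking noise comparable to the resting speed,
decoded occupancies shift slightly toward faster states; group contrasts
are unaffected because both groups share the noise floor.

## Problem sizes and determinism

Routine tests use scaled inputs chosen to exercise each property
clearly: 20–70 s recordings for unit tests, a full 5-minute 9000-frame
recording for the state-recovery check, 100-seed power/type-I runs at the
study's group sizes (28/32), and 300–500-seed calibration loops for the
uniformity and estimator-bias checks. All randomness flows from explicit
seeds; rerunning any pipeline command with the same config and seed
reproduces byte-identical CSV outputs (reports contain no timestamps).

## Known limitations

- The mixed ANCOVA is restricted to two within-subject levels (exact
  decomposition); three-level designs go through `mixed_anova` without a
  covariate.
- The binomial z classification inherits the normal approximation's
  anticonservatism at N = 50.
- Turning detection consumes the wrapped difference series as given; it
  does not gate on movement speed, so slow head sweeps while stationary
  count as turns if sustained past 45°.
- The pipeline's per-recording HMM is fit independently per subject;
  occupancies are comparable across subjects only when recordings share
  frame rate and tracking quality.
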
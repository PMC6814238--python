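# Methods

## Rating traces

A trial's raw record is a dial-event log: timestamps (seconds from clip
onset) paired with the new dial position in [-1, 1], emitted only when the
position changes. The cursor starts at the scale midpoint (neutral, 0).
Traces are built by **zero-order hold** on the grid t_i = i/f, i = 0..n-1,
with f = 10 Hz and n = round(duration x f) = 300 for a 30-s clip: sample i
takes the position of the latest event at or before t_i, or 0 before the
first event. Zero-order hold, not interpolation, because the physical
cursor *is* the rating and holds its position between updates; the neutral
start is likewise physical. Events are valid on [0, duration); the last
grid point is (n-1)/f = 29.9 s. Raw device units are mapped affinely so
device maximum -> +1, minimum -> -1, midpoint -> 0.

## Reliability

For each rate-group (observer, clip), Pearson r between test and retest
traces; constant traces make r undefined and such pairs are dropped and
counted, never imputed. Per-observer averages use the Fisher z transform
(atanh, mean, normal-theory CI from SD(z)/sqrt(k), tanh back); r = +/-1 is
clipped to 1 - 1e-7 before atanh. The scaled distance score is

    L2 = 1 - ||X - Y|| / sqrt(n),

which is 1 for identical vectors and -1 at the maximal distance 2*sqrt(n)
(all +1 vs all -1); it is applied to traces and to each observer's
per-category overall-rating vectors. Unlike r it is sensitive to level and
amplitude and is unaffected by autocorrelation. L2 scores are averaged
arithmetically (mean and median); the category comparison of per-observer
means uses the Wilcoxon signed-rank test (exact null for small samples
without ties, normal approximation otherwise).

## Temporal variability

rmsd = sqrt(mean(d_i^2)) over the n-1 first differences d_i = X_{i+1} - X_i,
in rating units per 0.1-s sample. Taking the divisor as the number of
difference terms keeps the constant-trace case exactly 0. For mixed models
rmsd is log-transformed (natural log); zero-rmsd trials (no dial movement)
are excluded from the log scale and counted. The interpretive reference is
the rmsd of a logarithmic rise spanning the full scale,
r(t) = 2 log10(1 + 9t/T) - 1, sampled on the standard grid; the functional
form is a configurable default — its exact shape is a presentation anchor,
not an estimated quantity.

Response styles: k-means (squared-Euclidean objective, 50 restarts, seeded)
on each observer's median rmsd per category (a 2-vector per observer); k is
chosen from 2..5 by maximal mean silhouette (Euclidean). Cluster labels are
ordered so cluster 0 has the larger mean rmsd ("fast responders"). A best
silhouette below 0.45 flags the solution as degenerate: k-means on
structureless single-Gaussian 2-D data already yields silhouettes around
0.35-0.40, so only values clearly above that null range indicate real
styles.

Because the dial mechanism couples two parameters, "dial responsiveness" is
defined mechanistically: the median rmsd a given (tau, dead-zone)
configuration produces on fixed standard-amplitude reference inputs. A long
lag lowers rmsd by smoothing; a wide dead zone *raises* it by converting
the same travel into rare large jumps — so neither parameter alone orders
observers, but this derived score does, and parameter-recovery tests check
the observed median rmsd against it.

## Agreement and taste decomposition

MM1 (mean-minus-one): each observer's rating vector correlated with the
element-wise mean of the other N-1 observers — over stimuli within one
(category, session, group) cell for overall ratings, over time within one
clip for traces. Undefined (constant-vector) scores are dropped with
counts. Continuous MM1 is aggregated over clips within observer by Fisher z
before condition-level Fisher-z summaries, mirroring the overall-rating
granularity.

The variance decomposition is a moment estimator on matched test/retest
participants x stimuli matrices (population-variance convention
throughout):

    sigma2_e = Var(test - retest) / 2          test-retest noise
    m        = (test + retest) / 2             cell means
    V_rep    = Var(m) - sigma2_e / 2           repeatable variance
    V_shared = (P Var_s(mean_p m) - V_rep - sigma2_e/2) / (P - 1)
    V_indiv  = V_rep - V_shared

The shared term subtracts the finite-P inflation of the group-mean
variance: substituting expectations, E[Var_s(group mean)] = V_sh +
(V_ind + sigma2_e/2)/P, makes the estimator exact in expectation. Negative
estimates are clipped at 0 and counted; V_shared is additionally capped at
V_rep. Fractions are reported against total = V_rep + sigma2_e and sum
to 1. The estimator is validated purely by synthetic recovery (50% shared
variance recovered within +-0.1 at P=25, S=30); no claim is made that it
matches any particular published variant.

## Mixed models and regressions

All two-level factors are sum-coded (+1/-1: dance, test, rate positive), so
a main-effect coefficient is half the difference of the two cell means in a
balanced design. Crossed random effects are fitted by REML via variance
components: one grouping level spanning all rows with indicator-coded
participant and stimulus columns, plus by-participant slope components
(factor code x participant indicators). Slopes are independent of
intercepts — the slope-intercept correlation a full covariance fit would
estimate is not modelled. Preset structures: overall ratings and continuous
MM1 use participant + stimulus intercepts with a by-participant category
slope; overall MM1 uses participant intercepts with category and session
slopes; log-rmsd (retest only) uses participant + stimulus intercepts with
a category slope. Optimization is L-BFGS with a derivative-free Powell
restart when a fit ends non-converged (typical when a variance component
sits at the zero boundary); non-convergence is reported, never hidden. An
all-constant outcome short-circuits to an explicit degenerate fit (zero
slopes and components).

Significance uses |t| >= 1.96 (two-tailed 5%, normal approximation).
Marginal R2 = Var(X beta) / (Var(X beta) + sum of variance components +
residual); conditional R2 adds the component sum to the numerator.
Calibration: on 200 null replicates of a 10-observer x 10-stimulus design
the criterion rejects at ~7%, within the 2-9% band expected of the normal
approximation at this size.

Trait regressions are OLS with z-scored predictors (outcome unscaled), with
coefficient t/p, multiple and adjusted R2 and the overall F; rank-deficient
or constant-covariate designs raise.

## Motion energy

A Gabor jet is the vector of complex Gabor magnitudes sampled on a spatial
grid (defaults: 5 scales x 8 orientations, 10 x 10 interior grid, bandwidth
1 octave), L2-normalized per frame. Kernels are made exactly zero-mean, and
frames are reflect-padded before FFT convolution so every grid point sees a
full kernel support — together this makes jets exactly invariant to global
intensity offsets. A contrast-free frame yields the zero vector with a
flag. Framewise motion energy is the Euclidean distance between consecutive
jets; a sequence's score is the mean, and category distributions of scores
are compared with the two-sample KS test. Frequencies must suit the frame:
the default lowest scale (0.05 cyc/px) needs frames of roughly 70 px or
more, and a frame smaller than the largest kernel is an error. Jet
extraction is verified against a dense brute-force convolution oracle to
1e-6 relative error.

## Synthetic experiment generator

The generator encodes exactly the structure the analyses test, with known
ground truth retained for recovery tests.

Latent value signals are Gaussian-smoothed white noise (length scale 3 s,
chosen as a plausible timescale of evaluative drift), standardized and
scaled to amplitude 0.4. Each stimulus draws one shared signal plus a mean
level (SD 0.2); each (observer, stimulus) pair draws one individual signal
plus the observer's stable offsets (overall bias and per-category affinity,
SD 0.25 each). The momentary latent value is

    w * shared + (1 - w) * individual + category shift + session noise,

clipped to [-1, 1], with w the observer's shared-taste weight. Shared and
individual components are drawn once and reused across sessions; session
noise (smooth, observer-specific SD) is the only cross-session difference,
and it keeps its natural random time-mean so a session-level change in
liking also moves the overall judgment — this is what couples overall and
continuous reliability across observers. Folding the stable offsets into
the individual component (scaled by 1 - w) keeps w = 1 populations exactly
identical across observers. Stable offsets (SD 0.25) deliberately exceed
the stimulus-shared level variance (SD 0.2): the emulated regime is one
where most repeatable taste is individual, with overall-MM1 means near
0.35-0.55.

The dial is a first-order lag (time constant tau, median 1 s, lognormal
sigma 0.7 spanning fast responders to slow integrators) tracking the latent
value, discretized at the sampling rate; an event is emitted only when the
lagged target departs from the current position by more than the dead zone
(uniform 0.01-0.10). The mechanism is deterministic given the latent trace.
The overall judgment is the time mean of the latent trace plus noise (SD
uniform 0.05-0.15) — a neutral default; peak-end or endpoint integration
rules are plausible alternatives left unimplemented, so no conclusion about
how real observers form overall judgments is encoded. Session noise SD is
uniform 0.05-0.40, wide enough that reliability genuinely ranks observers.

Trait covariates follow a stated linear model: positive affect loads +1.0
on the observer's mean bias; anhedonia loads +0.3 on log tau (slower,
flatter dial use); aesthetic responsiveness loads +1.0 on centered w;
category-preference items load +1.0 on the matching affinity; negative
affect and anxiety are pure noise. Each adds independent Gaussian noise
(SD 0.08-0.20), keeping every stated loading recoverable but not trivial.

All randomness is a pure function of the configured seed: every stream is
keyed by (seed, stream tag, stable 31-bit hashes of the participant and
stimulus ids), so any single trace regenerated in isolation matches the
full-experiment run, and identical configurations give bit-identical
datasets.

What the generator does **not** emulate: real clip content and event
structure (no time-locked features for observers to agree on beyond the
smooth shared signal), drift or learning across a session, block order,
non-Gaussian rating distributions, floor/ceiling usage habits, or any
relation between overall judgments and trace shape beyond the time mean.
Passing recovery tests therefore shows the estimators are consistent under
the assumed structure — not that real data satisfies that structure.

## Problem sizes and tolerances in the test suite

Parameter-recovery tests run the full design (25 + 25 observers, 30 clips)
over 10 seeds; rank-recovery thresholds are Spearman |rho| >= 0.8, the
category coefficient must fall inside its own 95% CI in at least 8 of 10
seeds, and the shared-variance fraction must be recovered within +-0.1.
Calibration uses 200 null mixed-model replicates on a reduced 10 x 10
design and 100 null trait regressions. Monotonicity checks (MM1 vs w,
reliability vs session noise) use three population levels x three seeds on
reduced designs, comparing level means. Unit examples use closed-form
values (e.g. rmsd of a 300-sample ramp = 2/299) computed independently in
the tests.

## Known limitations

- The variance decomposition assumes additivity (no observer x stimulus
  interaction structure beyond the individual term) and equal noise across
  cells.
- Random-slope/intercept correlations are not estimated; model-reduction
  workflows (PCA of random effects, likelihood-ratio pruning) are out of
  scope — random structures are fixed presets per analysis.
- The normal-approximation |t| criterion is anticonservative at small
  stimulus counts (~7% at 10 stimuli); degrees-of-freedom corrections are
  not applied.
- Gabor-bank parameters are conventional defaults, not fitted to any
  physiology; motion energy on real clips depends on frame extraction done
  upstream.
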
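# Methods

## Signal model and processing chain

A trial is a tandem-stance recording of the center of pressure (COP) on
a force plate at fs = 100 Hz, during which a pneumatic actuator delivers
unexpected lateral pushes at the pelvis. The analysis treats the COP as
two channels in mm — mediolateral (ML) and anteroposterior (AP) — plus a
TTL-like trigger channel that records the electrical valve command.
When only raw plate channels are available, COP is formed as
cop_x = −My/Fz, cop_y = Mx/Fz (m → mm), with a configurable floor on
|Fz| below which the quotient is rejected as unreliable. The plate-axis
to body-axis mapping (default x→ML, y→AP) and COP units are schema
configuration, since plate conventions are instrument specific.

Processing order: filter the full recording, then locate onsets, then
epoch. Filtering before epoching keeps filter edge transients away from
the analysis window.

### Filtering

Zero-phase low-pass Butterworth, cutoff 10 Hz, order 4 per pass,
applied forward–backward (scipy `filtfilt`, odd-reflection padding of
3·(order+1) samples). Forward–backward application doubles the
effective order and squares the magnitude response, so the gain at the
cutoff is exactly 1/2 and the net phase is zero. The filter order and
padding are configuration defaults (the dominant posturography
convention), not fixed constants of the method.

### Onsets and epochs

Perturbation contact (t = 0) is the trigger's rising threshold crossing
plus the actuator's mechanical travel time, rounded to the nearest
sample. The delay is a required, rig-specific configuration value with
no default; the synthetic rig uses 0.03 s. Re-crossings within a
refractory gap (default 0.5 s) are treated as contact bounce and
merged. A recording is excluded when the number of detected events
differs from the protocol's expectation (default 3 per trial).

Epochs span −0.4 to 2.0 s (241 samples at 100 Hz) with t = 0 exactly on
the onset sample. The ML channel is multiplied by the per-event
perturbation direction (±1 along ML) so the force direction reads
positive; AP is anterior-positive. Per-event directions come from
recording metadata, falling back to a configured constant. Epochs whose
window overruns the recording are dropped, not truncated, because every
feature needs the complete 0–0.4 s response window.

Baseline: the per-axis mean over the closed window −0.35 to −0.2 s
(16 samples at 100 Hz) is subtracted; correcting twice is a state
error unless explicitly forced (in which case it is a no-op).

### Features

Over the closed compensatory window 0–0.4 s (41 samples):

- **D-COP, T-COP** — maximum of the signed, baseline-corrected signal
  and its time; ties go to the earliest sample. A response moving only
  against the perturbation yields D ≈ 0 at the window start.
- **V-COP** — peak signed velocity toward the positive direction
  (an absolute-peak mode is available behind configuration). Velocity
  is `np.gradient` with `edge_order=2` *on the windowed segment*:
  central differences inside, second-order one-sided stencils at the
  window edges. Differencing the whole epoch instead would straddle the
  onset corner (flat baseline meets rising response) and bias the peak
  velocity low by roughly 12% at 100 Hz; the windowed second-order
  stencil recovers the analytic peak of the closed-form test response
  to better than 0.5%.
- **RMS** — square root of the time-average of x² over the window,
  evaluated by trapezoidal rule. A plain arithmetic mean over the
  closed window would double-count one endpoint and bias the value low
  by ≈ 1/(2n) (−1.2% for a 4-period sinusoid at these settings); the
  trapezoidal form is second-order accurate against the continuous RMS
  and exact for integer-period sinusoids.

Note that the 10 Hz low-pass materially attenuates the *velocity*
transient of sharply rising responses (≈ −34% on the synthetic
surrogate's onset corner at its default parameters) while leaving peak
displacement and its timing essentially untouched (< 0.2%, exact
sample). Recovery tests therefore compare pipeline V-COP and RMS
against a filtered-truth oracle — the same filter applied to an
independently constructed clean series — while D-COP and T-COP are
compared against the raw analytic truth.

Per participant and session, features are aggregated across the
surviving perturbation epochs by the arithmetic mean (median was
considered and rejected: with ≤ 3 epochs per trial the mean is the
conventional, lower-variance choice). Exclusion, never imputation:
an empty epoch list excludes that participant/session.

## Statistics

### Split-plot ANOVA

Balanced design, one between-subject factor (group, 2 levels) crossed
with one within-subject factor (time, 2 levels), subjects nested in
groups. Sums of squares by the classical mean decomposition:

    SS_total = SS_group + SS_subj(group) + SS_time + SS_group×time + SS_residual

F(group) uses MS_subj(group) as its error term; F(time) and the
interaction use MS_residual. Partial eta-squared is
SS_effect / (SS_effect + SS_of_its_error_term), classified at
0.01 / 0.06 / 0.14. With two within-subject levels sphericity holds
trivially, so no correction is applied. Unbalanced or incomplete tables
are rejected rather than approximated — the target design is balanced,
and Type-II/III decompositions are out of scope. The implementation is
verified in tests against an independent nested least-squares (design
matrix projection) route and against `pingouin.mixed_anova`.

### Simple effects and Shaffer's procedure

The post-hoc family is the four cell-mean equalities: time within each
group (paired t) and group at each time (pooled two-sample t; Welch
optional, off by default for the balanced design). The tests are
two-sided. The degenerate all-differences-zero contrast returns t = 0,
p = 1; zero variance around a nonzero mean is an error.

Shaffer's modified sequentially rejective Bonferroni procedure compares
the i-th smallest p-value with α/tᵢ, where tᵢ is the maximum number of
hypotheses that can be simultaneously true given that i−1 have been
rejected. The logical constraint is supplied either as a preset or as a
predicate over hypothesis subsets; attainable truth-set cardinalities
are found by enumeration. For the 2×2 family, any three equalities
imply the fourth, so the attainable counts are {0, 1, 2, 4} and the
divisor sequence is (4, 2, 2, 1) — strictly sharper than Holm's
(4, 3, 2, 1) from step two on. With no constraints the procedure
reduces exactly to Holm. On this family the counting form coincides
with full Bonferroni closed testing (property-tested against a
brute-force enumeration oracle). Adjusted p-values follow the
running-max convention max_{j≤i}(tⱼ·p₍ⱼ₎) capped at 1, so
"adjusted p < α" reproduces the sequential decisions.

### Power

Power of an F test is P(F′(df1, df2, λ) > F_crit(α)) with F′ the
noncentral F distribution. The design mapping from Cohen's f and the
repeated-measure correlation ρ follows the common repeated-measures
convention, with m measures and total N:

    between:              λ = N·m·f² / (1 + (m−1)ρ),  df = (a−1, N−a)
    within / interaction: λ = N·m·f² / (1 − ρ),       df = (m−1 resp. (a−1)(m−1), (N−a)(m−1))

For m = 2 under the additive random-intercept model these are the exact
noncentralities of the split-plot F statistics, not approximations
(derivable from the variance of the subject means and of the paired
differences). ρ defaults to 0.5 and is exposed, because a-priori N
depends strongly on it; `required_sample_size` reports the (df, λ)
mapping it used alongside the minimal balanced N. Post-hoc achieved
power converts observed η²ₚ to f² = η²ₚ/(1−η²ₚ) and applies the same
mapping at the realized sample size.

## Synthetic data

The generator exists so that every stage has a known ground truth; its
defaults are the study conditions the pipeline targets.

- **Response surrogate** x(t) = d·(t/τ)·e^{1−t/τ} (t ≥ 0): smooth,
  single-peaked, with closed-form features — peak d at t = τ, peak
  velocity d·e/τ at t → 0⁺. Default d = 12 mm, τ = 0.15 s.
- **Sway noise**: Gaussian noise shaped by the same 10 Hz low-pass
  family, rescaled to a target SD (default 1 mm, well below the
  response peak). It emulates quiet-stance sway bandwidth, not its
  long-range correlations.
- **Recordings**: 60 s, three events at uniform random times with a
  minimum 5 s gap (via the order-statistics construction), random ±1 ML
  directions, AP response = 0.5 × ML response plus independent noise
  (lateral pushes also evoke AP excursions), trigger edge one
  mechanical delay (0.03 s) before contact.
- **Trial tables**: value = grand + e_g·c_g + e_t·c_t + e_gt·c_g·c_t +
  b_i + ε with ±½ effect coding (so each `effect_*` equals the marginal
  mean difference), participant intercept b_i ~ N(0, sd_between²),
  residual ε ~ N(0, sd_within²).
- **Studies**: 9 participants per group (mirroring an 18-participant
  analysis set), per-participant baseline d ~ N(12, 2²) mm,
  session-to-session jitter SD 1 mm, and a configurable post-only delta
  on the device group's d (−3 mm, a 25% reduction, in the end-to-end
  detection condition).

All generators are deterministic under their seed. What passing tests
show: the pipeline recovers known parameters, the test statistics have
their nominal null behavior, and injected effects are detected with the
expected power. What they do not show: robustness to real-data
pathologies the surrogate lacks — drift, heteroscedastic sway,
direction-dependent asymmetries, actuator force variability, or
non-Gaussian participant heterogeneity.

## Numerical choices and degenerate inputs

- Window endpoints are closed intervals on the sample grid; indices are
  derived with round-to-nearest to keep −0.35 s and 0.4 s exactly on
  the 100 Hz grid.
- Ties in argmax resolve to the earliest sample; `np.argmax` provides
  this.
- Tiny negative sums of squares from cancellation are clamped at 0.
- All-constant tables, zero-variance contrasts with nonzero means,
  η²ₚ = 1, cutoffs at or above Nyquist, too-short series, and epochs
  overrunning the recording all raise typed errors rather than
  returning NaN.
- Monte-Carlo checks in the test suite use fixed seeds; problem sizes
  (200 GLM-agreement tables, 500 Shaffer vectors, 5000 null tables,
  100k noncentral-F draws, 200 end-to-end replicates) were chosen to
  put the Monte-Carlo standard error well inside each asserted
  tolerance.

## Known limitations

- The a-priori sample size for a given Cohen's f depends on the
  effect-family and ρ convention; the implementation exposes these
  assumptions rather than privileging one published N.
- Onset detection requires a trigger channel; detecting perturbations
  from COP kinematics alone is out of scope.
- No frequency-domain sway measures, no mixed-model (REML) estimation,
  no unbalanced designs.
- The COP-from-force conversion omits the plate-thickness origin
  correction by default (no plate geometry is assumed); a configuration
  hook exists in the schema for rigs that need it.
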
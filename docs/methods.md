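# Methods

## Scientific setting

Serial structural MRI is the standard way to quantify brain atrophy in
neurodegenerative disease. Many image-analysis pipelines turn a pair or
series of scans into either *indirect* change (subtract two independently
measured volumes) or *direct* change (a joint measurement over a registered
pair, e.g. a boundary shift integral). Techniques are usually ranked by the
sample size a hypothetical disease-modification trial would need if its
outcome were that technique's measure of change. This package implements
the statistical machinery for such an evaluation on a fixed longitudinal
cohort design: two groups (Alzheimer's disease cases and elderly controls)
scanned at nine visits over two years (0, 2, 6, 12, 26, 38, 52, 78, 104
weeks), with duplicate back-to-back scans at three visits (baseline, 6 and
38 weeks) — up to 12 scans and 66 scan pairs per subject.

All analyses work on the `100·ln(volume)` scale. Differences on this scale
approximate percent change while being multiplicatively symmetric, so a
measured loss and its reverse negate exactly. Atrophy is negative;
ventricular "atrophy" is expansion and stays positive internally.

## Reliability statistics

Three diagnostics quantify the plausibility of a technique before any
modelling:

* **Short-interval change.** Standardized change
  `c = 100·ln(V_r/V_b)` over same-day duplicate scans and over the
  two-week repeat, where true change is negligible; summarized by the mean
  with a one-sample two-tailed t-test against zero and a t-based 95% CI.
* **Symmetry.** `d_sym = 100·(fwd − neg_bwd) / (0.5·(fwd + neg_bwd))`
  comparing a forward direct measure with its negated backward companion.
* **Transitivity.** `d_trans = 100·(c_AC − (c_AB + c_BC)) /
  (0.5·(c_AC + c_AB + c_BC))` comparing a long direct measure with the sum
  of the two chained measures covering the same interval.

The ratio denominators are signed averages exactly as defined; when the
average change is essentially zero (|denominator| below 1e-12 relative to
scale) the ratio is undefined, flagged and excluded from summaries with a
count, rather than redefined. Because small denominators produce heavy
tails, symmetry and transitivity are summarized by the median with an
exact binomial order-statistic 95% confidence interval (the distribution-
free interval from Binomial(n, ½) order statistics; chosen because it
makes no shape assumptions and is exact at small n).

## Mixed model for repeated volumes

For one group and structure, with subject `i`, visit `j`, scan `k`:

    y_ijk = α_i + (β + b_i)·t_ij + d_ij + e_ijk
    b_i ~ N(0, σ_b²),  d_ij ~ N(0, σ_d²),  e_ijk ~ N(0, σ_e²)

`α_i` are fixed subject levels, `β` the mean rate (%/yr), `b_i` random
slopes, `d_ij` random visit effects (identified by the duplicate-scan
visits) and `e_ijk` scan-level error. Implied variances:

* difference over Δt: `Δt²σ_b² + 2σ_d² + 2σ_e²`
* rate over Δt: `σ_b² + (2σ_d² + 2σ_e²)/Δt²`

The within-subject part shrinks as 1/Δt² with follow-up; the
between-subject part is the floor. The aggregate within-subject variance
reported alongside σ_b² is `σ_w² = 2σ_d² + 2σ_e²`, the one-year rate
parameterization.

## Mixed model for repeated direct changes

The direct measure over the ordered pair (j₁,k₁)→(j₂,k₂) is

    c = (β + b_i)(t_ij₂ − t_ij₁) − u_ij₁ + u_ij₂ − v_ij₁k₁ + v_ij₂k₂ + w

with signed visit effects `u ~ N(0, σ_u²)`, signed scan effects
`v ~ N(0, σ_v²)` and a pair residual `w ~ N(0, σ_w²)` capturing the
imperfect additivity of direct measures. Because one subject's pairs share
visit and scan effects with signs depending on whether the pair starts or
ends there, the cross-pair covariance is

    Cov(p, q) = σ_b²·Δt_p·Δt_q + σ_u²·Σ_j sign_p(j)·sign_q(j)
                + σ_v²·Σ_k sign_p(k)·sign_q(k) + σ_w²·1[p=q]

Same-day pairs lose the visit term (the two signs cancel) and therefore
identify σ_v² and σ_w²; they are included in fits. Only forward measures
enter the model: backward measures are near-duplicates of the forward ones
and double-entry would fabricate precision; they are used exclusively by
the symmetry diagnostic.

## Estimation

Both models are estimated by REML. The volume model carries one fixed
intercept per subject, so ordinary maximum likelihood would bias the
variance components; the direct model uses the same criterion for
consistency. Fixed effects are profiled out by GLS, and the criterion is
Harville's restricted likelihood

    −2ℓ_R = (N−p)·log 2π + log|Σ| + log|X'Σ⁻¹X| − log|X'X| + y'Py

computed blockwise over subjects, with subjects sharing a visit schedule
evaluated together. The `−log|X'X|` convention makes ℓ_R equal the exact
log-density of any orthonormal basis of error contrasts, which the test
suite verifies against a dense `scipy` construction at 1e-6.

Numerical choices:

* Optimization over log-variances with analytic gradients (the standard
  trace/quadratic-form identities). Full-data fits use three starts — a
  method-of-moments estimate, a tenth and tenfold of it — through L-BFGS-B
  with a Nelder-Mead polish when a line search aborts at the optimum.
  Convergence tolerance is 1e-8 on the criterion.
* Warm-started refits (the bootstrap's resamples and jackknife) use
  safeguarded Fisher scoring on the expected information with
  backtracking, falling back to L-BFGS-B when it stalls. This is purely a
  speed optimization; both paths satisfy the same first-order tolerance.
* Components driven below 1e-8 are truncated to exactly zero and flagged
  as boundary estimates (`boundary` in the fit report); non-convergence is
  reported via a flag, never silently.
* Constrained variants pin σ_b² = σ_d² (volume) or σ_b² = σ_u² (direct)
  to zero; they are the fallback when near-zero components derail
  convergence on bootstrap resamples.

## Sample sizes for trials

For a two-arm trial measuring change over follow-up `t` with a treatment
assumed to remove a fraction `f` (default 0.25) of the *excess* rate over
healthy ageing, 80% power, two-sided α = 0.05:

    ES = (β_case − β_control) / √Var(rate_case at t)
    N_per_arm = 2·(1.960 + 0.842)² / (f·|ES|)²

`Var(rate_case)` comes from the case-group model only, exactly as the
effect-size definition prescribes; the control fit contributes only its
mean rate. By default the printed two-decimal z-values are used so the
formula is reproduced literally; `exact_quantiles=True` switches to full
precision. Per-arm N is rounded up (conservative; the rounding convention
is otherwise arbitrary) and the total is twice that.

## Bootstrap inference

Uncertainty in sample sizes uses a non-parametric bootstrap with subjects
as the resampling unit, stratified by group so every resample holds the
original group sizes (default 2000 resamples; the test suite and the
reproduction script use 200–500 to keep desk-scale runtimes). Confidence
intervals are constructed on the effect-size scale — far more symmetric
than the N scale — with the BCa adjustment: bias correction `z₀` from the
fraction of resampled estimates below the point estimate and acceleration
`a` from a leave-one-subject-out jackknife (the subject, not the
observation, is the exchangeable unit). The N interval maps the |ES|
endpoints through the sample-size formula, so the lower |ES| bound gives
the upper N bound; resamples whose effect size flips sign are counted and
flagged, since the mapping is monotone only in |ES|.

Failed resamples (non-convergence or a degenerate case variance) are
dropped and counted. If they exceed 1% of resamples, the control-group
model is refit in constrained form and the whole bootstrap re-run — the
standard remedy when a variance component sits near zero — and the result
is marked `fallback_used`.

Head-to-head comparisons of two techniques measured on the same subjects
share resample indices (same seed), making per-resample effect-size
differences paired. Technique A is judged better at the 5% level when more
than 97.5% of resamples favor it (larger |ES|, hence smaller N); ties
split evenly, so a technique against itself sits at exactly 0.5. No
multiplicity correction is applied across comparisons.

## Synthetic data

The generator emulates the cohort design exactly: 46 cases and 23
controls on the nine-visit schedule, with all subjects completing 52 weeks
and every other subject attending the 78/104-week extension (the real
cohort's extension attendance was partial; 50% alternating is a fixed,
documented stand-in). One master seed spawns an independent substream per
subject, so changing one subject's attendance never perturbs another's
draws. Volumes are produced by the exact volume-model equation and
exponentiated; direct changes by the exact direct-model equation, with the
backward measure equal to the negated forward measure plus optional
mean-zero asymmetry noise (`symmetry_noise_sd`, default 0 — emulating a
symmetry-enforcing technique).

Default parameters are the study conditions: mean rates at the midpoints
of the ranges reported for published techniques on this kind of cohort
(whole brain −1.8 / −0.51 %/yr for AD / controls, ventricles +7.0 / +2.3,
hippocampi −4.0 / −0.9) and AD variance components from representative
technique estimates — whole brain 0.47 between / 0.19 within (a
boundary-shift-integral-style measure, used for both the volume and direct
presets), ventricle 17.17/3.94 (volume) and 3.18/0.82 (direct),
hippocampi 4.24/12.00 and 4.60/10.05 (volume), 10.00/6.93 and 8.50/7.51
(direct). Published tables report only the aggregate within-subject
variance, so the presets partition it: volumes split 2σ_d²:2σ_e² as
0.6:0.4 (visit-level error typically dominates scan-level); direct
measures split 2σ_u²:2σ_v²:σ_w² as 0.5:0.3:0.2 (direct registration
shrinks visit/scan error and leaves a small non-additivity residual). No
published control-group components exist, so controls share the
technique's within components (error belongs to the technique, not the
disease) with between-subject variance scaled by 0.25 (controls are more
homogeneous). Baseline levels default to order-of-magnitude volumes
(brain ~1100 ml, ventricles ~40 ml, hippocampi ~3 ml); they do not enter
rate inference.

What the generator does *not* emulate: scanner drift, segmentation
failures, non-linear trajectories, informative dropout, or any image-level
mechanism — all measurement error is subsumed in the d/e/u/v/w terms, and
attendance is ignorable. Passing tests therefore demonstrate that the
estimators and intervals are correct *under the assumed model*, not that
the model describes any particular real technique.

## Problem sizes used in validation

The test suite verifies the variance formulas by Monte Carlo at 10⁴
subjects per interval; parameter recovery over 200 simulated cohorts of
100 subjects per model; BCa interval coverage over 200 datasets of 24
subjects (three-visit schedule) at 500 resamples using the direct-change
pipeline; and the reliability t-test size over 1000 replicate cohorts.
The reproduction script (`scripts/acceptance.py`) analyses one
full-design cohort per structure with 500 bootstrap resamples. These
sizes are the package's validation choices; every threshold was fixed
with the study conditions, not fitted to outcomes.

## Known limitations

* The week→year conversion is fixed at 7/365.25; any monotone convention
  would do, this one is documented.
* Exclusion lists operate on scan identity only; there is no outlier
  detection — exclusions are inputs.
* Letter-coded exclusion files ("subject_F") assume letters follow the
  chronological scan order of the full schedule; cohorts with a different
  naming convention must supply explicit (subject, visit, scan) columns.
* Each (structure, group) is modelled independently; there is no joint
  multivariate model, no interim-visit design, and no missing-data
  adjustment beyond ignorable attendance.
* The percent-scale direct-change reader assumes changes are relative to
  the pair's start scan volume.
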
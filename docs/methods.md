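# Methods

## Problem and data

An intrathecally injected gadolinium contrast agent acts as a CSF tracer:
when it first reaches a brain region via the perivascular (glymphatic)
route, the region's T1-weighted MRI signal begins to rise. Signals are
normalized by a reference-ROI T1 intensity on the same scan to remove
scan-to-scan grayscale rescaling, giving a dimensionless ratio near 1.
Each subject has one pre-injection scan (coded with negative hours) and a
few post-injection scans at irregular clinical times up to roughly 7 h;
next-day scans show established enrichment everywhere and are excluded from
fitting (`max_time_h`, default 7.0 h). Observations are pooled over
subjects per (cohort, region): sampling is too sparse per subject for
subject-level breakpoints, so the estimand is a group-level
first-appearance time.

## Model

    y_i = beta0 + beta1 * max(t_i - psi, 0) + eps_i,   eps_i ~ N(0, sigma^2)

The pre-breakpoint segment is constrained horizontal: before the tracer
arrives there is no signal trend to model. The breakpoint `psi` (hours) is
the first-appearance time; `beta1` (units/h) is a crude proxy for influx
rate. Negative `psi` estimates are representable (the time axis includes
pre-injection scans) and flag regions with effectively instantaneous
enrichment, where a single-breakpoint model is at its limit.

## Estimation

`psi` enters nonlinearly; the estimator is the iterative linearization used
by segmented-regression software: regress `y` on `[1, U, V]` with
`U = max(t - psi_k, 0)`, `V = -1[t > psi_k]`, and update
`psi_{k+1} = psi_k + gamma/delta` where `delta, gamma` are the U and V
coefficients. Observations exactly at the breakpoint are assigned to the
plateau (`t <= psi`).

Two safeguards make the iteration reliable on sparse, noisy series:

* **Monotone step-halving.** The raw update can two-cycle across a
  data-point kink of the profile RSS. Each proposed step is halved until
  the exact profile RSS (closed-form two-parameter fit at the proposed
  breakpoint) does not increase, which forces convergence to a local
  minimum.
* **Profile-scan initialization** (`psi_init="auto"`). The profile RSS can
  have several near-equal local minima. The closed-form profile is scanned
  over a fine grid (`init_grid_h`, default 0.01 h) plus all
  inter-observation midpoints, and the iteration starts at the argmin —
  a deterministic analogue of the bootstrap-restart heuristic used
  elsewhere for the same problem. If that run still fails, restarts from
  interior quantiles of the observed times are tried and the minimum-RSS
  convergent solution kept.

The breakpoint is constrained to the observed time range with at least
`min_points_per_segment` (default 2) observations per side. A fit needs at
least 4 observations, at least one at/before injection and two after.
Degenerate cases raise typed errors: a flat signal is an unidentifiable
breakpoint; a constant outcome has no defined R².

Inference: at convergence `gamma ~ 0` and the delta method gives
`SE(psi) = SE(gamma)/|delta|` from the OLS covariance of the linearized
fit; the CI is `psi ± z_{0.975} SE` with the normal quantile 1.959964.
R² is `1 − RSS/TSS` of the piecewise fit about the grand mean. Pooling
ignores within-subject correlation, so the SE can be somewhat optimistic;
the generator's `subject_sd` knob exists to study exactly that.

## Between-cohort comparison

Per region, two cohorts are fitted separately and compared with
`z = (psi_B − psi_A) / sqrt(SE_A^2 + SE_B^2)`, two-sided normal p. The SEs
come from the separate fits, not the joint model, because the joint model's
shared baseline can absorb small systematic pre-detection signal
differences between groups and distort the breakpoints. p-values are
adjusted over the full region family (17 regions in the bundled published
table) with Holm's step-down procedure at alpha = 0.05 (delegated to
statsmodels, cross-checked against the sequential-rejection definition in
tests).

The joint two-group model — one shared `beta0`, per-group `psi_g` and
`beta1_g` — is fitted by the same linearization with both breakpoints
updated simultaneously, and is intended for plotting both cohorts on a
common baseline.

**Reconstruction mode.** When only published group estimates with 95% CIs
are available (the typical situation for the bundled table, whose raw scans
are not public), each breakpoint's SE is back-solved as
`(CI_high − CI_low) / (2 × 1.959964)` and the same z machinery applies.
This reproduces the bundled table's printed difference rows to their
printed precision.

## Synthetic cohorts

`simulate_cohort` emulates the study design: per subject, nominal scan
times (default schedule −0.5, 0.3, 2, 4, 6 h: one pre-injection scan plus
post scans near the clinical 0/2/4/6 h slots) jittered by
`N(0, jitter_sd²)` with `jitter_sd = 0.25` h, truncated so pre-injection
scans stay negative and post scans non-negative; signal
`beta0 + b_s + beta1·max(t − psi, 0) + N(0, sigma²)` with an optional
subject intercept `b_s ~ N(0, subject_sd²)` (default 0, matching the pooled
estimator's assumption). Defaults — `beta0 = 1.0` normalized units,
`beta1 = 0.05`/h, `sigma = 0.02`, 30 subjects — were chosen to resemble the
dispersion of real normalized-T1 series; they are configurable and not
claimed to be any study's exact values. Everything is reproducible from the
scenario seed via independent child streams per replicate.

What the generator does **not** emulate: pharmacokinetic curvature of real
uptake (real post-arrival rises are not exactly linear), within-subject
correlation by default, missing scans, region-to-region correlation, and
the 24–48 h clearance phase. Passing simulation checks therefore validates
the estimator under its own assumptions, not the biology.

`run_scenarios` fits every replicate and reports bias, RMSE, 95%-CI
coverage, mean CI width and the convergence count; non-convergent
replicates are excluded from the metrics and counted. Problem sizes used in
the validation suite — 200 cohorts for the grid-oracle agreement check,
500 replicates for coverage and for the z-test size, 200 per rung of the
3/5/9 scans-per-subject ladder — give Monte-Carlo error small enough for
the acceptance bands while keeping the whole suite fast.

## Numerical choices

* Grid-oracle tie-break: smallest breakpoint wins (first-appearance
  semantics).
* Convergence: |breakpoint update| < `tol` (default 1e-6 h), cap
  `max_iter = 50`.
* Slopes with |delta| < 1e-12 are treated as zero (unidentifiable).
* Aggregation of atlas segments into composite regions: unweighted mean by
  default, volume-weighted when volumes are supplied (the right choice
  depends on how the upstream pipeline defined composite signals; both are
  provided).
* Cohort demographics: pooled-variance two-sample t test (df n1+n2−2) and
  Pearson chi-square without continuity correction.

## Known limitations

* Pooled fitting understates SEs when within-subject correlation is
  present; CI coverage checks use the generator's matching assumption.
* A single breakpoint cannot represent instantaneous enrichment followed by
  saturation; such regions surface as near-zero or negative breakpoints
  with wide CIs.
* The delta-method CI is first-order; coverage in simulations sits near but
  not exactly at 95% (typically 0.93–0.96 at ~150 pooled observations).
* The z test assumes independent cohorts and normal breakpoint estimates;
  with very few subjects the normal approximation degrades.
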
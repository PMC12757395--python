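# glymseg

Estimating **when a CSF tracer first reaches a brain region** from sparse
longitudinal MRI.

After an intrathecal injection of a gadolinium contrast agent, the agent acts
as a cerebrospinal-fluid tracer: as it enters a brain region through the
glymphatic (perivascular) route, the region's normalized T1 signal starts to
rise. Subjects are scanned once before injection and a handful of times over
the following ~7 hours, at irregular clinical times. `glymseg` estimates the
time of first tracer appearance per region — a group-level proxy for
glymphatic influx — and compares it between patient cohorts.

## Model

For pooled observations `(t_i, y_i)` of one (cohort, region) pair, the mean
is a plateau followed by a line:

    mu(t) = beta0 + beta1 * max(t - psi, 0)

* `beta0` — baseline normalized T1 level (flat before the tracer arrives),
* `psi`   — the **breakpoint** (hours since injection): first tracer appearance,
* `beta1` — post-arrival slope (signal units per hour), a proxy for influx rate.

`psi` enters nonlinearly and is estimated by iterative linearization: at each
iterate the signal is regressed on `U = max(t - psi, 0)` and
`V = -1[t > psi]`, and the breakpoint is updated by `gamma/delta` (the V and
U coefficients), with monotone step-halving on the exact profile RSS and a
closed-form profile scan to pick the starting value. At convergence the delta
method gives `SE(psi) = SE(gamma)/|beta1|` and a normal-quantile 95% CI.

Cohorts are compared per region with a z test on the difference of their two
breakpoints (`SE_diff = sqrt(SE_ref^2 + SE_iih^2)`), with Holm step-down
adjustment across the region family. A shared-baseline joint model (one
common plateau level, separate breakpoints and slopes per group) is available
as an alternative presentation.

## Worked example

```python
import numpy as np
from glymseg import SegmentedRegressor, SimulationScenario, simulate_cohort

# noiseless plateau-then-slope data: baseline 10 until 2 h, then slope 5/h
t = np.array([-1., 0., 1., 2., 3., 4., 5., 6.])
y = np.where(t <= 2, 10.0, 10.0 + 5.0 * (t - 2))
m = SegmentedRegressor().fit(t.reshape(-1, 1), y)
print(round(m.psi_, 6), round(m.beta0_, 6), round(m.beta1_, 6), m.r2_)
# 2.0 10.0 5.0 1.0

# a realistic synthetic cohort: 30 subjects, 5 scans each, tracer at 1.5 h
series, _ = simulate_cohort(SimulationScenario(true_psi=1.5, seed=42))
m = SegmentedRegressor().fit(series)
print(round(m.psi_, 2), tuple(round(v, 2) for v in m.ci_psi_))
# 1.47 (1.3, 1.64)
```

The first fit recovers the noiseless truth exactly (breakpoint 2.0 h,
baseline 10, slope 5/h, R² = 1). The second estimates the tracer-arrival
time at 1.47 h with 95% CI (1.30, 1.64) — covering the true 1.5 h.

The command line wraps the same machinery:

```sh
glymseg fit      --input scans.csv --out results/ --plots
glymseg compare  --input scans.csv --cohorts REF,IIH --out results/
glymseg simulate --scenarios scenarios.ini --seed 1 --out results/
```

`scans.csv` is long-format with columns
`subject_id, cohort, region, time_h, signal` (optionally
`raw_t1, ref_t1, volume_mm3`); scans later than 7 h after injection are
excluded from fitting by default.

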
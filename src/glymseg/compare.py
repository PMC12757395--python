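"""Between-cohort comparison of first-appearance times.

Two cohorts (e.g. reference subjects vs idiopathic-intracranial-hypertension
patients) are fitted separately per region; the difference of their
breakpoints is tested with a z statistic built from the two delta-method
standard errors, and the family of per-region p-values is adjusted with
Holm's step-down procedure to control the family-wise error rate.

An expanded joint model — a single shared baseline level with separate
breakpoints and slopes per group — is available as an alternative
presentation; the z test itself always consumes the two separate fits, since
the shared baseline can absorb small systematic pre-detection signal
differences between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .data import RegionSeries
from .exceptions import (
    EmptyFamilyError,
    InsufficientDataError,
    NonConvergenceError,
    UnidentifiableBreakpointError,
)
from .segmented import SegmentedRegressor, _SLOPE_EPS, _design, r_squared


@dataclass(frozen=True)
class BreakpointEstimate:
    """A breakpoint with its standard error, the minimal input to the z test.

    Useful when only published estimates with confidence intervals are
    available: :meth:`from_ci` back-solves the SE from the interval width.
    """

    psi: float
    se_psi: float
    conf: float = 0.95

    def __post_init__(self):
        if not np.isfinite(self.psi) or not np.isfinite(self.se_psi) or self.se_psi <= 0:
            raise ValueError("breakpoint estimate needs finite psi and positive SE")

    @classmethod
    def from_ci(cls, psi: float, ci_low: float, ci_high: float, conf: float = 0.95):
        """Reconstruct the SE from a symmetric normal-quantile interval:
        SE = (high − low) / (2 z)."""
        if ci_high <= ci_low:
            raise ValueError("ci_high must exceed ci_low")
        z = stats.norm.ppf(0.5 + conf / 2.0)
        return cls(psi=float(psi), se_psi=float((ci_high - ci_low) / (2.0 * z)), conf=conf)

    @property
    def ci(self):
        z = stats.norm.ppf(0.5 + self.conf / 2.0)
        return (self.psi - z * self.se_psi, self.psi + z * self.se_psi)


@dataclass(frozen=True)
class BreakpointComparison:
    """Difference of two cohorts' first-appearance times for one region."""

    region: str
    psi_ref: float
    psi_iih: float
    se_ref: float
    se_iih: float
    diff: float
    se_diff: float
    ci_diff: tuple
    z: float
    p: float
    p_holm: float | None = None


def _as_estimate(model) -> BreakpointEstimate:
    if isinstance(model, BreakpointEstimate):
        return model
    if getattr(model, "converged_", False) is not True:
        raise NonConvergenceError("comparison requires a converged model")
    return BreakpointEstimate(psi=model.psi_, se_psi=model.se_psi_)


def compare_breakpoints(model_ref, model_iih, conf: float = 0.95, region: str = "") -> BreakpointComparison:
    """z test on the difference of two independently estimated breakpoints.

    ``diff = psi_iih − psi_ref``; its SE is the quadrature sum of the two
    delta-method SEs, the z statistic is diff/SE with a two-sided
    standard-normal p, and the CI uses the normal quantile at ``conf``.

    Inputs may be fitted :class:`~glymseg.segmented.SegmentedRegressor`
    instances or :class:`BreakpointEstimate` records.
    """
    ref = _as_estimate(model_ref)
    iih = _as_estimate(model_iih)
    diff = iih.psi - ref.psi
    se_diff = float(np.hypot(ref.se_psi, iih.se_psi))
    z = diff / se_diff
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = stats.norm.ppf(0.5 + conf / 2.0)
    return BreakpointComparison(
        region=region,
        psi_ref=ref.psi,
        psi_iih=iih.psi,
        se_ref=ref.se_psi,
        se_iih=iih.se_psi,
        diff=float(diff),
        se_diff=se_diff,
        ci_diff=(float(diff - q * se_diff), float(diff + q * se_diff)),
        z=float(z),
        p=min(p, 1.0),
    )


def holm_adjust(p_values, alpha: float = 0.05):
    """Holm step-down adjustment over the full region family.

    Returns ``(adjusted, flags)`` in the original order; ``flags`` marks
    family-wise significance at ``alpha``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise EmptyFamilyError("no p-values to adjust")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


def attach_holm(comparisons, alpha: float = 0.05):
    """Return the comparisons with ``p_holm`` filled in across the family."""
    comps = list(comparisons)
    adjusted, _ = holm_adjust([c.p for c in comps], alpha=alpha)
    return [replace(c, p_holm=float(a)) for c, a in zip(comps, adjusted)]


def comparison_table(comparisons, alpha: float = 0.05, decimals: int | None = None) -> pd.DataFrame:
    """Region-by-region comparison table with Holm flags.

    ``decimals`` (e.g. 1) rounds the printed columns the way a results table
    would; full precision is kept when it is None.
    """
    comps = attach_holm(comparisons, alpha=alpha)
    df = pd.DataFrame(
        {
            "region": [c.region for c in comps],
            "psi_ref": [c.psi_ref for c in comps],
            "psi_iih": [c.psi_iih for c in comps],
            "diff": [c.diff for c in comps],
            "ci_low": [c.ci_diff[0] for c in comps],
            "ci_high": [c.ci_diff[1] for c in comps],
            "z": [c.z for c in comps],
            "p": [c.p for c in comps],
            "p_holm": [c.p_holm for c in comps],
        }
    )
    df["significant_holm"] = df["p_holm"] <= alpha
    if decimals is not None:
        for col in ("psi_ref", "psi_iih", "diff", "ci_low", "ci_high"):
            df[col] = df[col].round(decimals)
    return df


class JointSegmentedRegressor(BaseEstimator):
    """Two-group segmented model with a shared baseline level.

    Mean function per group ``g``:

        mu_g(t) = beta0 + beta1_g * max(t - psi_g, 0)

    i.e. one common pre-breakpoint horizontal line, but separate breakpoints
    and post-break slopes. Fitted by the same iterative linearization as the
    single-group model, updating both breakpoints simultaneously.

    ``fit(X, y)`` expects ``X`` with two columns: time (hours) and a group
    code; the two distinct codes are taken in sorted order as groups 0 and 1.

    Attributes
    ----------
    beta0_ : shared baseline level.
    psi_ : ndarray (2,) breakpoints per group.
    beta1_ : ndarray (2,) post-break slopes per group.
    se_psi_ : ndarray (2,) delta-method SEs.
    groups_ : the two group labels, sorted.
    rss_, r2_, converged_, n_iter_ : diagnostics.
    """

    def __init__(
        self,
        psi_init="auto",
        max_iter: int = 50,
        tol: float = 1e-6,
        conf: float = 0.95,
        n_restarts: int = 10,
        min_points_per_segment: int = 2,
    ):
        self.psi_init = psi_init
        self.max_iter = max_iter
        self.tol = tol
        self.conf = conf
        self.n_restarts = n_restarts
        self.min_points_per_segment = min_points_per_segment

    def _joint_design(self, t, g, psis):
        cols = [np.ones_like(t)]
        for k in (0, 1):
            mask = (g == k).astype(float)
            cols.append(np.maximum(t - psis[k], 0.0) * mask)  # U_k
        for k in (0, 1):
            mask = (g == k).astype(float)
            cols.append(-(t > psis[k]).astype(float) * mask)  # V_k
        return np.column_stack(cols)

    def _refit(self, t, g, psis):
        """LS fit at fixed breakpoints (no V columns): beta0, slopes, rss."""
        cols = [np.ones_like(t)]
        for k in (0, 1):
            cols.append(np.maximum(t - psis[k], 0.0) * (g == k))
        x = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(x, y_ := self._y, rcond=None)
        resid = y_ - x @ coef
        return coef, float(resid @ resid)

    def _iterate(self, t, g, y, psi0, ranges):
        # step-halving on the joint profile RSS, as in the single-group model
        psis = np.array(
            [np.clip(psi0[k], ranges[k][0], ranges[k][1]) for k in (0, 1)], dtype=float
        )
        _, rss = self._refit(t, g, psis)
        for it in range(1, self.max_iter + 1):
            x = self._joint_design(t, g, psis)
            coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            if rank < 5:
                return None
            deltas, gammas = coef[1:3], coef[3:5]
            if np.any(np.abs(deltas) < _SLOPE_EPS):
                return None
            steps = gammas / deltas
            new = psis + steps
            new_rss = None
            for _halving in range(40):
                inside = all(ranges[k][0] <= new[k] <= ranges[k][1] for k in (0, 1))
                if inside:
                    _, new_rss = self._refit(t, g, new)
                    if new_rss <= rss + 1e-12 * (1.0 + rss):
                        break
                steps = steps / 2.0
                new = psis + steps
            else:
                return None
            if not np.all(np.isfinite(new)):
                return None
            if np.max(np.abs(new - psis)) < self.tol:
                return new, float(new_rss), it
            psis, rss = new, float(new_rss)
        return None

    def fit(self, X, y=None):
        if isinstance(X, (tuple, list)) and len(X) == 2 and isinstance(X[0], RegionSeries):
            s0, s1 = X
            t = np.concatenate([s0.time_h, s1.time_h])
            y = np.concatenate([s0.signal, s1.signal])
            g = np.concatenate([np.zeros(s0.n_obs, int), np.ones(s1.n_obs, int)])
            self.groups_ = (s0.cohort, s1.cohort)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("X must have two columns: time, group")
            t = X[:, 0]
            labels = X[:, 1]
            uniq = np.unique(labels)
            if uniq.size != 2:
                raise ValueError("exactly two groups required")
            g = (labels == uniq[1]).astype(int)
            y = np.asarray(y, dtype=float)
            self.groups_ = tuple(uniq.tolist())
        self._y = y

        ranges = []
        single = SegmentedRegressor(min_points_per_segment=self.min_points_per_segment)
        for k in (0, 1):
            tk = t[g == k]
            if tk.size < 4:
                raise InsufficientDataError(f"group {k} has {tk.size} < 4 observations")
            if not np.any(tk <= 0):
                raise NonConvergenceError(
                    "shared-baseline collinearity: a group has no pre-breakpoint "
                    "observations"
                )
            ranges.append(single._admissible_range(np.sort(tk)))

        if self.psi_init == "auto":
            psi0 = [float(np.median(t[(g == k) & (t > 0)])) for k in (0, 1)]
        else:
            psi0 = [float(p) for p in np.atleast_1d(self.psi_init)] * (
                1 if np.atleast_1d(self.psi_init).size == 2 else 2
            )

        solutions = []
        first = self._iterate(t, g, y, psi0, ranges)
        if first is not None:
            solutions.append(first)
        else:
            qs = np.linspace(0.2, 0.8, max(self.n_restarts, 1))
            for q in qs:
                init = [float(np.quantile(t[g == k], q)) for k in (0, 1)]
                res = self._iterate(t, g, y, init, ranges)
                if res is not None:
                    solutions.append(res)
            if not solutions:
                raise NonConvergenceError("joint model: no convergent initialization")

        psis, rss, n_iter = min(solutions, key=lambda s: s[1])
        coef, rss = self._refit(t, g, psis)
        if np.any(np.abs(coef[1:3]) < _SLOPE_EPS):
            raise UnidentifiableBreakpointError("a group's post-break slope vanishes")

        ols = sm.OLS(y, self._joint_design(t, g, psis)).fit()
        se_gamma = np.asarray(ols.bse)[3:5]
        tss = float(np.sum((y - y.mean()) ** 2))

        self.psi_ = np.asarray(psis, dtype=float)
        self.beta0_ = float(coef[0])
        self.beta1_ = np.asarray(coef[1:3], dtype=float)
        self.se_psi_ = se_gamma / np.abs(self.beta1_)
        self.rss_ = rss
        self.r2_ = r_squared(rss, tss)
        self.n_iter_ = n_iter
        self.converged_ = True
        del self._y
        return self

    def predict(self, X):
        """Per-group piecewise mean; ``X`` has (time, group) columns."""
        check_is_fitted(self, "psi_")
        X = np.asarray(X, dtype=float)
        t, labels = X[:, 0], X[:, 1]
        g = (labels == self.groups_[1]).astype(int)
        out = np.full(t.shape, self.beta0_)
        for k in (0, 1):
            m = g == k
            out[m] += self.beta1_[k] * np.maximum(t[m] - self.psi_[k], 0.0)
        return out


def fit_joint_two_group(series_ref: RegionSeries, series_iih: RegionSeries, **config):
    """Fit the shared-baseline two-group model to a pair of RegionSeries."""
    return JointSegmentedRegressor(**config).fit((series_ref, series_iih))


def grid_profile_oracle_2d(series_ref, series_iih, grid_ref, grid_iih,
                           min_points_per_segment: int = 2):
    """Brute-force RSS search over the (psi_ref, psi_iih) plane for the
    shared-baseline joint model. Returns ((psi_ref, psi_iih), min_rss)."""
    t = np.concatenate([series_ref.time_h, series_iih.time_h])
    y = np.concatenate([series_ref.signal, series_iih.signal])
    g = np.concatenate(
        [np.zeros(series_ref.n_obs, int), np.ones(series_iih.n_obs, int)]
    )
    best = None
    for p0 in np.asarray(grid_ref, float):
        for p1 in np.asarray(grid_iih, float):
            ok = True
            for k, p in ((0, p0), (1, p1)):
                tk = t[g == k]
                if (tk <= p).sum() < min_points_per_segment or (tk > p).sum() < min_points_per_segment:
                    ok = False
            if not ok:
                continue
            x = np.column_stack(
                [np.ones_like(t)]
                + [np.maximum(t - p, 0.0) * (g == k) for k, p in ((0, p0), (1, p1))]
            )
            coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            rss = float(resid @ resid)
            if best is None or rss < best[1] - 1e-15:
                best = ((float(p0), float(p1)), rss)
    if best is None:
        raise ValueError("no admissible candidate pair")
    return best
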
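"""Plateau-then-slope segmented regression with breakpoint confidence interval.

Model
-----
The mean of the normalized T1 signal as a function of time ``t`` (hours since
intrathecal injection) is piecewise linear with a horizontal first segment:

    mu(t) = beta0                          for t <= psi
    mu(t) = beta0 + beta1 * (t - psi)      for t >  psi

equivalently ``mu(t) = beta0 + beta1 * max(t - psi, 0)``. The breakpoint
``psi`` is the time the flat baseline turns into a rising slope and is read
as the first appearance of the tracer in the region (first glymphatic
influx). The zero pre-break slope is a hard model constraint, not a tested
hypothesis: before the tracer arrives there is nothing to drive the signal.

Estimation
----------
``psi`` enters the mean nonlinearly, so the fit uses iterative linearization
(the scheme behind the R ``segmented`` package). At the current iterate
``psi_k`` the mean is expanded to first order in ``psi``, giving a linear
regression of the signal on

    U = max(t - psi_k, 0)        (slope term)
    V = -1[t > psi_k]            (breakpoint-correction term)

with coefficients ``(beta0, delta, gamma)``. The update is
``psi_{k+1} = psi_k + gamma / delta``; at a fixed point ``gamma ~ 0``,
``delta`` is the post-break slope and the delta method gives
``SE(psi) = SE(gamma) / |delta|``. The 95% CI uses the standard-normal
quantile. If the first iteration fails (diverges, cycles, or leaves the
admissible range), the fit restarts from breakpoints spread over interior
quantiles of the observed times and keeps the minimum-RSS convergent
solution.

A closed-form grid search over candidate breakpoints
(:func:`grid_profile_oracle`) provides a brute-force check on the iterative
estimator: at each fixed ``psi`` the model is an ordinary two-parameter
least-squares problem.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import RegionSeries
from .exceptions import (
    DegenerateR2Error,
    EmptyGridError,
    InsufficientDataError,
    NonConvergenceError,
    UnidentifiableBreakpointError,
)

_SLOPE_EPS = 1e-12  # |delta| below this is treated as a vanishing slope


def _design(t: np.ndarray, psi: float) -> np.ndarray:
    """Linearized design matrix [1, U, V] at breakpoint psi."""
    u = np.maximum(t - psi, 0.0)
    v = -(t > psi).astype(float)
    return np.column_stack([np.ones_like(t), u, v])


def _piecewise_ls(t: np.ndarray, y: np.ndarray, psi: float):
    """Closed-form least squares of y on [1, max(t-psi, 0)].

    Returns (beta0, beta1, rss).
    """
    u = np.maximum(t - psi, 0.0)
    x = np.column_stack([np.ones_like(t), u])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


class SegmentedRegressor(RegressorMixin, BaseEstimator):
    """Plateau-then-slope segmented regression of signal on time.

    Parameters
    ----------
    psi_init : float or "auto"
        Starting breakpoint. ``"auto"`` starts at the median of the
        positive (post-injection) observed times.
    max_iter : int
        Iteration cap for the linearization loop.
    tol : float
        Convergence tolerance on the breakpoint update, in hours.
    conf : float
        Confidence level for the breakpoint interval (normal quantile).
    n_restarts : int
        Number of fallback initializations, spread over interior quantiles
        of the observed times, used only when the first run fails.
    min_points_per_segment : int
        Minimum observations required on each side of the breakpoint.
    allow_psi_outside_observed : bool
        If False (default) the breakpoint is kept inside the observed time
        range during iteration.
    init_grid_h : float
        Resolution (hours) of the closed-form profile scan used to choose
        the starting breakpoint when ``psi_init="auto"``.

    Attributes
    ----------
    beta0_ : float
        Baseline (pre-breakpoint) signal level.
    beta1_ : float
        Post-breakpoint slope, signal units per hour.
    psi_ : float
        Breakpoint, hours since injection — the first-appearance estimate.
    se_psi_ : float
        Delta-method standard error of ``psi_``.
    ci_psi_ : tuple of float
        ``conf``-level confidence interval for ``psi_``.
    sigma2_ : float
        Residual variance (rss / (n - 3)).
    r2_ : float
        Coefficient of determination of the piecewise fit.
    rss_, n_obs_, n_iter_, converged_ : fit diagnostics.

    Examples
    --------
    >>> import numpy as np
    >>> t = np.array([-1., 0., 1., 2., 3., 4., 5., 6.])
    >>> y = np.where(t <= 2, 10.0, 10.0 + 5.0 * (t - 2))
    >>> m = SegmentedRegressor().fit(t.reshape(-1, 1), y)
    >>> round(m.psi_, 6), round(m.beta0_, 6), round(m.beta1_, 6)
    (2.0, 10.0, 5.0)
    """

    def __init__(
        self,
        psi_init="auto",
        max_iter: int = 50,
        tol: float = 1e-6,
        conf: float = 0.95,
        n_restarts: int = 10,
        min_points_per_segment: int = 2,
        allow_psi_outside_observed: bool = False,
        init_grid_h: float = 0.01,
    ):
        self.psi_init = psi_init
        self.max_iter = max_iter
        self.tol = tol
        self.conf = conf
        self.n_restarts = n_restarts
        self.min_points_per_segment = min_points_per_segment
        self.allow_psi_outside_observed = allow_psi_outside_observed
        self.init_grid_h = init_grid_h

    # -- helpers ---------------------------------------------------------

    def _validate_xy(self, X, y):
        if isinstance(X, RegionSeries):
            if not X.is_fittable():
                raise InsufficientDataError(
                    f"series ({X.cohort}, {X.region}) needs >= 4 observations "
                    "with >= 1 at or before injection and >= 2 after"
                )
            t, y = X.time_h, X.signal
        else:
            t = np.asarray(X, dtype=float)
            if t.ndim == 2:
                if t.shape[1] != 1:
                    raise ValueError("X must be a single time column")
                t = t[:, 0]
            y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and signal must have equal length")
        if t.size < 4:
            raise InsufficientDataError(
                f"segmented fit needs >= 4 observations, got {t.size}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input")
        return t, y

    def _admissible_range(self, t_sorted: np.ndarray):
        m = self.min_points_per_segment
        n = t_sorted.size
        if n < 2 * m:
            raise InsufficientDataError(
                f"need >= {2 * m} observations for {m} per segment, got {n}"
            )
        # t <= psi goes to the plateau, so psi >= t_(m) keeps m points left
        # and psi < t_(n-m+1) keeps m points right.
        lo = t_sorted[m - 1]
        hi = np.nextafter(t_sorted[n - m], -np.inf)
        if hi < lo:
            raise InsufficientDataError("observed times too tied to place a breakpoint")
        return lo, hi

    def _profile_init(self, t, y, lo, hi):
        """Starting breakpoint from a closed-form profile-RSS scan.

        The RSS profile over the breakpoint is cheap to evaluate exactly
        (two-parameter least squares at each fixed candidate) but can carry
        several near-equal local minima, so a single arbitrary start can
        converge to the wrong one. Scanning a fine grid plus the
        inter-observation midpoints and starting the iteration at the best
        candidate plays the role the bootstrap-restart heuristic plays in
        other segmented-regression implementations, deterministically.
        """
        if not (np.isfinite(lo) and np.isfinite(hi)):
            lo, hi = float(np.min(t)), float(np.max(t))
        uniq = np.unique(t)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        cand = np.concatenate(
            [[lo, hi], mids, np.arange(lo, hi, self.init_grid_h)]
        )
        cand = np.unique(cand[(cand >= lo) & (cand <= hi)])
        # vectorized LS of y on [1, max(t - c, 0)] for every candidate c
        u = np.maximum(t[None, :] - cand[:, None], 0.0)
        n = t.size
        su, suu = u.sum(axis=1), (u * u).sum(axis=1)
        sy, suy = y.sum(), u @ y
        det = n * suu - su * su
        with np.errstate(divide="ignore", invalid="ignore"):
            beta1 = (n * suy - su * sy) / det
        beta1 = np.where(np.isfinite(beta1), beta1, 0.0)
        beta0 = (sy - beta1 * su) / n
        resid = y[None, :] - beta0[:, None] - beta1[:, None] * u
        rss = (resid * resid).sum(axis=1)
        return float(cand[int(np.argmin(rss))])

    def _iterate(self, t, y, psi0, lo, hi):
        """One linearization run. Returns (psi, rss, n_iter, slope) or None.

        The raw update ``gamma / delta`` can overshoot or two-cycle across a
        data-point kink in the RSS profile, so the step is halved until the
        profile RSS does not increase (monotone descent), which forces the
        step below ``tol`` at a local minimum.
        """
        psi = float(np.clip(psi0, lo, hi))
        _, _, rss = _piecewise_ls(t, y, psi)
        for it in range(1, self.max_iter + 1):
            x = _design(t, psi)
            coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            delta, gamma = coef[1], coef[2]
            if rank < 3 or abs(delta) < _SLOPE_EPS:
                # flat post-break segment: breakpoint not identified here
                return None
            step = gamma / delta
            new = psi + step
            new_rss = None
            for _halving in range(40):
                if self.allow_psi_outside_observed or (lo <= new <= hi):
                    _, _, new_rss = _piecewise_ls(t, y, new)
                    if new_rss <= rss + 1e-12 * (1.0 + rss):
                        break
                step /= 2.0
                new = psi + step
            else:
                return None
            if not np.isfinite(new):
                return None
            if abs(new - psi) < self.tol:
                return float(new), float(new_rss), it, float(delta)
            psi, rss = float(new), float(new_rss)
        return None

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y=None):
        """Fit the segmented model.

        ``X`` may be an (n, 1) array of times with ``y`` the signals, a 1-D
        time array, or a :class:`~glymseg.data.RegionSeries` (in which case
        ``y`` is ignored).
        """
        t, y = self._validate_xy(X, y)
        t_sorted = np.sort(t)
        lo, hi = self._admissible_range(t_sorted)
        if self.allow_psi_outside_observed:
            lo, hi = -np.inf, np.inf

        if self.psi_init == "auto":
            psi0 = self._profile_init(t, y, lo, hi)
        else:
            psi0 = float(self.psi_init)

        solutions = []
        first = self._iterate(t, y, psi0, lo, hi)
        if first is not None:
            solutions.append(first)
        else:
            # restart from interior quantiles of the observed times
            qs = np.linspace(0.1, 0.9, max(self.n_restarts, 1))
            for q in qs:
                res = self._iterate(t, y, float(np.quantile(t, q)), lo, hi)
                if res is not None:
                    solutions.append(res)
            if not solutions:
                # distinguish a flat signal from a genuinely wandering fit
                _, b1_mid, _ = _piecewise_ls(t, y, float(np.median(t)))
                if abs(b1_mid) < 1e-8 and np.ptp(y) < 1e-8:
                    raise UnidentifiableBreakpointError(
                        "post-breakpoint slope indistinguishable from zero"
                    )
                profile = {
                    float(np.quantile(t, q)): _piecewise_ls(t, y, float(np.quantile(t, q)))[2]
                    for q in qs
                }
                raise NonConvergenceError(
                    "no convergent breakpoint initialization", rss_profile=profile
                )

        psi, rss, n_iter, _ = min(solutions, key=lambda s: (s[1], s[0]))

        # final inference at the converged breakpoint
        beta0, beta1, rss = _piecewise_ls(t, y, psi)
        if abs(beta1) < _SLOPE_EPS:
            raise UnidentifiableBreakpointError(
                "post-breakpoint slope indistinguishable from zero"
            )
        ols = sm.OLS(y, _design(t, psi)).fit()
        se_gamma = float(ols.bse[2])
        se_psi = se_gamma / abs(beta1)
        z = stats.norm.ppf(0.5 + self.conf / 2.0)

        tss = float(np.sum((y - y.mean()) ** 2))
        self.n_obs_ = int(t.size)
        self.psi_ = float(psi)
        self.beta0_ = beta0
        self.beta1_ = beta1
        self.se_psi_ = se_psi
        self.ci_psi_ = (float(psi - z * se_psi), float(psi + z * se_psi))
        self.rss_ = rss
        self.sigma2_ = rss / max(t.size - 3, 1)
        self.r2_ = r_squared(rss, tss)
        self.n_iter_ = n_iter
        self.converged_ = True
        self.time_range_ = (float(t_sorted[0]), float(t_sorted[-1]))
        return self

    def predict(self, X):
        """Piecewise mean at the requested times."""
        check_is_fitted(self, "psi_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self.beta0_ + self.beta1_ * np.maximum(t - self.psi_, 0.0)

    def summary_row(self) -> dict:
        """Flat record of the fit, convenient for tabular output."""
        check_is_fitted(self, "psi_")
        return {
            "psi": self.psi_,
            "ci_low": self.ci_psi_[0],
            "ci_high": self.ci_psi_[1],
            "se_psi": self.se_psi_,
            "beta0": self.beta0_,
            "beta1": self.beta1_,
            "r2": self.r2_,
            "n_obs": self.n_obs_,
            "converged": self.converged_,
        }


def fit_segmented(series, y=None, **config) -> SegmentedRegressor:
    """Fit a :class:`SegmentedRegressor` to a RegionSeries or (times, signals).

    Keyword arguments are estimator parameters (``tol``, ``conf``,
    ``max_iter``, ...). Returns the fitted estimator.
    """
    return SegmentedRegressor(**config).fit(series, y)


def grid_profile_oracle(series, y=None, grid=None, min_points_per_segment: int = 2):
    """Brute-force profile-RSS search over candidate breakpoints.

    For each candidate ``psi`` on the grid the two remaining parameters have
    a closed-form least-squares solution, so the profile RSS is exact. The
    candidate minimizing the RSS wins; ties go to the smallest breakpoint
    (first-appearance semantics).

    Parameters
    ----------
    series : RegionSeries or array of times
    y : signals when ``series`` is an array
    grid : strictly increasing candidate breakpoints
    min_points_per_segment : candidates leaving fewer observations on either
        side are inadmissible and dropped.

    Returns
    -------
    (psi_hat, rss_profile) where ``rss_profile`` is a dict
    {candidate: rss} over admissible candidates.
    """
    if isinstance(series, RegionSeries):
        t, y = series.time_h, series.signal
    else:
        t = np.asarray(series, dtype=float)
        y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise EmptyGridError("empty candidate grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    m = min_points_per_segment
    n_left = np.array([(t <= g).sum() for g in grid])
    admissible = (n_left >= m) & (t.size - n_left >= m)
    if not admissible.any():
        raise EmptyGridError("no admissible candidate on the grid")
    cand = grid[admissible]

    # vectorized closed-form LS for y ~ 1 + max(t - psi, 0) per candidate
    u = np.maximum(t[None, :] - cand[:, None], 0.0)  # (k, n)
    n = t.size
    su = u.sum(axis=1)
    suu = (u * u).sum(axis=1)
    sy = y.sum()
    suy = u @ y
    det = n * suu - su * su
    beta1 = (n * suy - su * sy) / det
    beta0 = (sy - beta1 * su) / n
    resid = y[None, :] - beta0[:, None] - beta1[:, None] * u
    rss = (resid * resid).sum(axis=1)

    best = int(np.argmin(rss))  # argmin takes the first == smallest psi on ties
    return float(cand[best]), dict(zip(cand.tolist(), rss.tolist()))


def r_squared(rss: float, tss: float) -> float:
    """Coefficient of determination 1 − rss/tss, clipped to [0, 1] only
    against floating-point dust (an intercept model cannot beat the mean)."""
    if tss <= 0:
        raise DegenerateR2Error("constant outcome: R^2 undefined (tss = 0)")
    r2 = 1.0 - rss / tss
    return float(min(max(r2, 0.0), 1.0))
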
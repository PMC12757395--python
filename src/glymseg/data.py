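"""Data model and tabular plumbing for intrathecal CSF-tracer MRI series.

The unit of analysis is a long-format table with one row per
(subject, region, scan): hours since intrathecal injection (negative for the
pre-injection scan) and the normalized T1 signal, i.e. the region's T1
intensity divided by the T1 intensity of a reference ROI on the same scan.
Observations are pooled over subjects into one :class:`RegionSeries` per
(cohort, region) pair, which is what the segmented model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateTestError,
    EmptySeriesError,
    InvalidReferenceError,
    MappingError,
    MissingCohortError,
)

REQUIRED_COLUMNS = ("subject_id", "cohort", "region", "time_h", "signal")
OPTIONAL_COLUMNS = ("raw_t1", "ref_t1", "volume_mm3")

#: Default post-injection cutoff in hours. Scans on the following day are
#: visually inspected upstream but excluded from breakpoint estimation.
DEFAULT_MAX_TIME_H = 7.0


@dataclass(frozen=True)
class RegionSeries:
    """Pooled observations for one (cohort, region) pair.

    Parameters
    ----------
    cohort, region : str
        Labels identifying the series.
    time_h : ndarray
        Hours since injection; negative values are pre-injection scans.
    signal : ndarray
        Normalized T1 signal (dimensionless ratio), same length as ``time_h``.
    n_subjects : int
        Number of distinct subjects contributing observations.
    """

    cohort: str
    region: str
    time_h: np.ndarray
    signal: np.ndarray
    n_subjects: int = 0

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("time_h and signal must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)):
            raise ValueError("time_h contains non-finite values")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "signal", y)

    @property
    def n_obs(self) -> int:
        return self.time_h.size

    def is_fittable(self, min_obs: int = 4) -> bool:
        """Whether a segmented fit can even be attempted: enough points,
        at least one at-or-before injection and two after."""
        return (
            self.n_obs >= min_obs
            and int(np.sum(self.time_h <= 0)) >= 1
            and int(np.sum(self.time_h > 0)) >= 2
        )


@dataclass(frozen=True)
class RegionMap:
    """Mapping from atlas segment names to composite region names.

    ``mode`` selects how member-segment signals are combined:
    ``"unweighted_mean"`` (default) or ``"volume_weighted_mean"``.
    """

    mapping: dict = field(default_factory=dict)
    mode: str = "unweighted_mean"

    def __post_init__(self):
        if self.mode not in ("unweighted_mean", "volume_weighted_mean"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")

    @classmethod
    def from_csv(cls, path, mode: str = "unweighted_mean") -> "RegionMap":
        """Read a two-column (segment, composite_region) CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("region map CSV needs two columns: segment, composite_region")
        seg, comp = df.columns[:2]
        return cls(mapping=dict(zip(df[seg].astype(str), df[comp].astype(str))), mode=mode)


def normalize_signal(raw_t1, ref_t1):
    """Normalized T1 signal: region T1 divided by the reference-ROI T1.

    Correcting by a reference ROI removes scan-to-scan grayscale rescaling,
    making intensities comparable across time points. Accepts scalars or
    arrays; broadcasting follows numpy rules.

    Raises
    ------
    InvalidReferenceError
        If any reference value is non-positive or non-finite.
    """
    raw = np.asarray(raw_t1, dtype=float)
    ref = np.asarray(ref_t1, dtype=float)
    if not np.all(np.isfinite(ref)) or np.any(ref <= 0):
        raise InvalidReferenceError("reference-ROI T1 must be finite and > 0")
    out = raw / ref
    return float(out) if out.ndim == 0 else out


def load_scan_table(path) -> pd.DataFrame:
    """Load a long-format scan CSV and validate it row by row.

    The header must contain ``subject_id, cohort, region, time_h, signal``;
    ``raw_t1, ref_t1, volume_mm3`` are optional. When both raw and reference
    T1 are present, the signal column is checked against their ratio. A
    missing ``signal`` is filled from raw_t1/ref_t1 when possible.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "signal"]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    if "signal" not in df.columns:
        if not {"raw_t1", "ref_t1"}.issubset(df.columns):
            raise ValueError("input CSV needs a signal column or raw_t1 + ref_t1")
        df["signal"] = np.nan

    have_raw = {"raw_t1", "ref_t1"}.issubset(df.columns)
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        t = row["time_h"]
        if not np.isfinite(t):
            raise ValueError(f"line {line}: time_h is not finite")
        sig = row["signal"]
        if have_raw and np.isfinite(row["raw_t1"]) and np.isfinite(row["ref_t1"]):
            ratio = normalize_signal(row["raw_t1"], row["ref_t1"])
            if np.isfinite(sig):
                if not np.isclose(sig, ratio, rtol=1e-9, atol=0.0):
                    raise ValueError(
                        f"line {line}: signal {sig} inconsistent with raw_t1/ref_t1 {ratio}"
                    )
            else:
                df.at[idx, "signal"] = ratio
        sig = df.at[idx, "signal"]
        if not np.isfinite(sig) or sig <= 0:
            raise ValueError(f"line {line}: signal must be finite and > 0")
    return df


def filter_scan_window(data, max_time_h: float = DEFAULT_MAX_TIME_H):
    """Restrict observations to the early-influx window ``time_h <= max_time_h``.

    Pre-injection scans (negative times) are always retained — they anchor
    the baseline plateau. Later scans (the ~24 h and ~48 h follow-ups) are
    dropped from model fitting. Order is preserved.

    Parameters
    ----------
    data : RegionSeries or pandas.DataFrame
    max_time_h : float
        Cutoff in hours, must be positive. Default 7.0.

    Returns
    -------
    (filtered, n_removed)

    Raises
    ------
    EmptySeriesError
        If nothing survives the cutoff.
    """
    if max_time_h <= 0:
        raise ValueError("max_time_h must be > 0")
    if isinstance(data, RegionSeries):
        keep = data.time_h <= max_time_h
        n_removed = int((~keep).sum())
        if not keep.any():
            raise EmptySeriesError(
                f"no observations at or before {max_time_h} h for "
                f"({data.cohort}, {data.region})"
            )
        out = RegionSeries(
            cohort=data.cohort,
            region=data.region,
            time_h=data.time_h[keep],
            signal=data.signal[keep],
            n_subjects=data.n_subjects,
        )
        return out, n_removed
    df = data
    keep = df["time_h"] <= max_time_h
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptySeriesError(f"no observations at or before {max_time_h} h")
    return df.loc[keep].copy(), n_removed


def aggregate_regions(df: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Combine per-segment rows into composite-region rows.

    For each (subject, cohort, time, composite region) the signal becomes the
    mean of the member-segment signals — volume-weighted when the map's mode
    is ``volume_weighted_mean`` and a ``volume_mm3`` column is present,
    otherwise unweighted. Deterministic given input order.

    Raises
    ------
    MappingError
        Naming the first segment absent from the map.
    """
    unmapped = sorted(set(df["region"].astype(str)) - set(region_map.mapping))
    if unmapped:
        raise MappingError(f"segment {unmapped[0]!r} has no composite-region mapping")
    out = df.copy()
    out["region"] = out["region"].astype(str).map(region_map.mapping)
    keys = ["subject_id", "cohort", "region", "time_h"]
    weighted = (
        region_map.mode == "volume_weighted_mean"
        and "volume_mm3" in out.columns
        and out["volume_mm3"].notna().all()
    )
    if weighted:
        def _agg(g):
            w = g["volume_mm3"].to_numpy(float)
            return pd.Series(
                {"signal": float(np.average(g["signal"].to_numpy(float), weights=w)),
                 "volume_mm3": float(w.sum())}
            )
        res = out.groupby(keys, sort=False).apply(_agg, include_groups=False).reset_index()
    else:
        agg = {"signal": "mean"}
        if "volume_mm3" in out.columns:
            agg["volume_mm3"] = "sum"
        res = out.groupby(keys, sort=False).agg(agg).reset_index()
    return res


def region_series(
    df: pd.DataFrame, cohort: str, region: str, max_time_h: float | None = None
) -> RegionSeries:
    """Extract the pooled :class:`RegionSeries` for one (cohort, region)."""
    sub = df[(df["cohort"] == cohort) & (df["region"] == region)]
    if sub.empty:
        if (df["cohort"] == cohort).sum() == 0:
            raise MissingCohortError(f"cohort {cohort!r} has no observations")
        raise EmptySeriesError(f"no observations for ({cohort!r}, {region!r})")
    series = RegionSeries(
        cohort=str(cohort),
        region=str(region),
        time_h=sub["time_h"].to_numpy(float),
        signal=sub["signal"].to_numpy(float),
        n_subjects=int(sub["subject_id"].nunique()),
    )
    if max_time_h is not None:
        series, _ = filter_scan_window(series, max_time_h)
    return series


def iter_region_series(df: pd.DataFrame, max_time_h: float | None = None):
    """Yield a RegionSeries per (cohort, region) pair, in input order."""
    seen = df[["cohort", "region"]].drop_duplicates()
    for cohort, region in seen.itertuples(index=False):
        yield region_series(df, cohort, region, max_time_h=max_time_h)


# --------------------------------------------------------------------------
# Cohort summary statistics (demographics-table plumbing)

def pooled_t_test(group_a, group_b):
    """Student's two-sample t test with pooled variance, two-sided.

    Returns ``(t, p, df)`` with df = n1 + n2 − 2. Raises
    :class:`DegenerateTestError` when both groups have zero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        # identical constants: t = 0/0
        raise DegenerateTestError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.statistic):
        raise DegenerateTestError("t statistic undefined (zero pooled variance)")
    return float(res.statistic), float(res.pvalue), int(a.size + b.size - 2)


def chi_square_test(counts):
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(statistic, p, df)`` with df = (r−1)(c−1).
    """
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0) or not np.all(np.isfinite(table)):
        raise ValueError("counts must be non-negative and finite")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def cohort_summary(values_by_group=None, counts=None):
    """Summarize a cohort comparison the way a demographics table does.

    Provide either ``values_by_group`` — a mapping of two group labels to
    numeric sequences (summarized as mean ± SD, compared with a pooled
    two-sample t test) — or ``counts`` — a 2-D contingency table (compared
    with Pearson's chi-square, no continuity correction).

    Returns a dict with per-group summaries, the test name, statistic and p.
    """
    if (values_by_group is None) == (counts is None):
        raise ValueError("provide exactly one of values_by_group or counts")
    if values_by_group is not None:
        if len(values_by_group) != 2:
            raise ValueError("values_by_group must contain exactly two groups")
        (la, a), (lb, b) = values_by_group.items()
        t, p, dof = pooled_t_test(a, b)
        return {
            "groups": {
                la: {"n": len(a), "mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1))},
                lb: {"n": len(b), "mean": float(np.mean(b)), "sd": float(np.std(b, ddof=1))},
            },
            "test": "t",
            "statistic": t,
            "p": p,
            "df": dof,
        }
    stat, p, dof = chi_square_test(counts)
    return {"counts": np.asarray(counts).tolist(), "test": "chi2",
            "statistic": stat, "p": p, "df": dof}
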
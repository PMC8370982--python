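"""Time-series containers and preprocessing shared by the whole package.

A :class:`RegimeSeries` holds one variable's observations within one labeled
dynamical regime on an evenly spaced time axis.  Regimes under comparison are
bundled into a :class:`RegimePair`.  Preprocessing mirrors the conventions of
the attractor-difference test: every series is standardized (mean 0, sd 1,
sample denominator) before embedding, a long series is split into two regimes
at a known breakpoint and each segment re-standardized independently, and
occasional missing observations are imputed with the smoothed mean of a
local-level (random walk plus observation noise) state-space model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Union

import numpy as np

from .exceptions import (
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidBreakpointError,
)

__all__ = [
    "RegimeSeries",
    "RegimePair",
    "standardize",
    "split_at_breakpoint",
    "impute_missing",
]

#: Relative tolerance on the constancy of the sampling interval.
_SPACING_RTOL = 1e-9
#: Tolerance on the mean/sd of a series claiming to be standardized.
_STANDARDIZED_ATOL = 1e-9
#: Minimum length of a regime segment that can still be embedded (E=1 needs
#: E_max + 2 = 3 points for leave-one-out dimension selection).
MIN_EMBEDDABLE_LENGTH = 3


@dataclass(frozen=True)
class RegimeSeries:
    """One variable's observations within one labeled dynamical regime.

    Parameters
    ----------
    values : ndarray
        Observations, finite floats.
    times : ndarray
        Strictly increasing, evenly spaced time index.
    regime_label : str
        Name of the dynamical regime the segment is hypothesized to belong to.
    variable_name : str
        Name of the observed variable.
    standardized : bool
        True once the series has been scaled to mean 0, sd 1 (sample sd).
    """

    values: np.ndarray
    times: np.ndarray
    regime_label: str = ""
    variable_name: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.ndim != 1 or times.ndim != 1:
            raise ValueError("values and times must be one-dimensional")
        if len(values) != len(times):
            raise ValueError(
                f"values (n={len(values)}) and times (n={len(times)}) differ in length"
            )
        if len(values) < 1:
            raise ValueError("a series must contain at least one observation")
        diffs = np.diff(times)
        if len(diffs) > 0:
            if np.any(diffs <= 0):
                raise ValueError("times must be strictly increasing")
            dt = diffs[0]
            if np.any(np.abs(diffs - dt) > _SPACING_RTOL * max(abs(dt), 1.0)):
                raise ValueError("times must be evenly spaced")
        if self.standardized and len(values) >= 2:
            if abs(float(np.mean(values))) > _STANDARDIZED_ATOL:
                raise ValueError("standardized series must have mean 0")
            if abs(float(np.std(values, ddof=1)) - 1.0) > _STANDARDIZED_ATOL:
                raise ValueError("standardized series must have sd 1")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        """Sampling interval (undefined for a single observation)."""
        if len(self.times) < 2:
            raise ValueError("sampling interval undefined for a single point")
        return float(self.times[1] - self.times[0])

    def with_values(self, values: np.ndarray, **changes) -> "RegimeSeries":
        """Copy of the series with new values (times and labels preserved)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)


#: A regime may be observed through one variable or several aligned variables.
SeriesBundle = Union[RegimeSeries, Mapping[str, RegimeSeries]]


def _bundle_variables(bundle: SeriesBundle) -> tuple[str, ...]:
    if isinstance(bundle, RegimeSeries):
        return (bundle.variable_name,)
    return tuple(sorted(bundle))


@dataclass(frozen=True)
class RegimePair:
    """The two labeled regimes being compared for dynamical difference."""

    regime_a: SeriesBundle
    regime_b: SeriesBundle

    def __post_init__(self) -> None:
        if _bundle_variables(self.regime_a) != _bundle_variables(self.regime_b):
            raise ValueError("the two regimes must observe the same variables")

    def _first(self, bundle: SeriesBundle) -> RegimeSeries:
        if isinstance(bundle, RegimeSeries):
            return bundle
        return next(iter(bundle.values()))

    @property
    def labels(self) -> tuple[str, str]:
        return (
            self._first(self.regime_a).regime_label,
            self._first(self.regime_b).regime_label,
        )


def standardize(series: RegimeSeries) -> RegimeSeries:
    """Scale a series to mean 0 and sample standard deviation 1.

    Uses the n-1 denominator.  Idempotent to floating precision; constant
    series cannot be standardized (they carry no dynamical signal) and raise
    :class:`DegenerateSeriesError`.
    """
    if len(series) < 2:
        raise InsufficientDataError("standardization requires at least 2 points")
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError(
            f"series {series.variable_name!r} in regime {series.regime_label!r} "
            "has zero variance and cannot be standardized"
        )
    z = (series.values - np.mean(series.values)) / sd
    return series.with_values(z, standardized=True)


def split_at_breakpoint(
    series: RegimeSeries,
    breakpoint_time: float,
    labels: tuple[str, str] = ("pre", "post"),
) -> RegimePair:
    """Split one series into two regimes at a known breakpoint.

    Observations with ``time <= breakpoint_time`` form the first regime, the
    rest the second.  Each segment is standardized independently, matching the
    convention that both regimes enter the test on a common scale.

    The breakpoint itself is taken from outside knowledge (breakpoint
    analysis, a known intervention); locating it is out of scope.
    """
    t = series.times
    if not (t[0] < breakpoint_time < t[-1]):
        raise InvalidBreakpointError(
            f"breakpoint {breakpoint_time} outside the observed range "
            f"[{t[0]}, {t[-1]}]"
        )
    mask = t <= breakpoint_time
    n_a = int(mask.sum())
    n_b = len(series) - n_a
    for n, lab in ((n_a, labels[0]), (n_b, labels[1])):
        if n < MIN_EMBEDDABLE_LENGTH:
            raise InsufficientDataError(
                f"segment {lab!r} has {n} points; at least "
                f"{MIN_EMBEDDABLE_LENGTH} are required for embedding"
            )
    seg_a = RegimeSeries(
        series.values[mask], t[mask], regime_label=labels[0],
        variable_name=series.variable_name,
    )
    seg_b = RegimeSeries(
        series.values[~mask], t[~mask], regime_label=labels[1],
        variable_name=series.variable_name,
    )
    return RegimePair(standardize(seg_a), standardize(seg_b))


def impute_missing(values_with_gaps: np.ndarray) -> np.ndarray:
    """Fill missing entries with the smoothed mean of a local-level model.

    The structural model is a random walk observed with noise (the minimal
    linear-Gaussian state-space model); its two variances are estimated by
    maximum likelihood on the observed entries and the Kalman smoother's
    posterior mean replaces each missing value.  Observed entries are
    returned unchanged.  Missing entries are encoded as NaN.
    """
    x = np.asarray(values_with_gaps, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional sequence")
    missing = np.isnan(x)
    observed = x[~missing]
    if observed.size == 0:
        raise DegenerateSeriesError("all values are missing; nothing to smooth")
    if not np.all(np.isfinite(observed)):
        raise ValueError("observed values must be finite")
    if not np.any(missing):
        return x.copy()
    if observed.size < 10:
        raise InsufficientDataError(
            f"imputation requires >= 10 observed values, got {observed.size}"
        )
    lead = int(np.argmax(~missing))
    trail = int(np.argmax(~missing[::-1]))
    if lead > 3 and trail > 3:
        raise InsufficientDataError(
            "gaps longer than 3 points at both ends cannot be smoothed reliably"
        )
    if np.ptp(observed) == 0.0:
        # Degenerate MLE limit: both variances collapse and the smoothed
        # level equals the constant.
        out = x.copy()
        out[missing] = observed[0]
        return out

    from statsmodels.tsa.statespace.structural import UnobservedComponents

    model = UnobservedComponents(x, level="local level")
    res = model.fit(disp=0)
    smoothed = np.asarray(res.smoothed_state[0])
    out = x.copy()
    out[missing] = smoothed[missing]
    return out
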
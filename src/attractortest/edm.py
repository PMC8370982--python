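"""Delay embedding and simplex-projection forecasting.

This module is the prediction machinery of the attractor-difference test.
A univariate series is embedded into delay vectors

    y(t) = < Y(t), Y(t-1), ..., Y(t-(E-1)) >          (lag tau = 1),

the set of which is the reconstructed attractor M of its regime.  Forecasts
are exponentially distance-weighted averages over the E+1 nearest library
vectors (simplex projection): one step ahead for the univariate mode,

    Yhat(t+1) | M = sum_m w_m Y_lib(t_m + 1),

and contemporaneous for the multivariate cross-map mode, where the embedding
of a predictor variable X maps onto a response variable Y at the same times,

    Yhat(t) | M = sum_m w_m Y_lib(t_m).

Weights follow u_m = exp(-d_m / d_1) normalized to sum to one, with d_1 the
distance to the nearest neighbor; exact zero-distance neighbors share the
weight equally (the continuity limit of the formula as d_1 -> 0).

The embedding dimension E is the only estimated parameter: it maximizes the
leave-one-out Pearson correlation between observations and one-step
self-forecasts, ties broken toward the smallest E.

Estimators follow scikit-learn conventions (:class:`SimplexForecaster`,
:class:`CrossMapForecaster`); the module-level functions are thin wrappers
kept for scripting convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DegenerateSeriesError, InsufficientDataError
from .series import RegimeSeries

__all__ = [
    "DelayVector",
    "ReconstructedAttractor",
    "NeighborSet",
    "ForecastResult",
    "embed",
    "embed_array",
    "neighbor_weights",
    "select_embedding_dimension",
    "simplex_forecast",
    "cross_map_forecast",
    "SimplexForecaster",
    "CrossMapForecaster",
]

DEFAULT_E_CEILING = 10


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DelayVector:
    """A single E-dimensional delay vector anchored at one time index."""

    anchor_time: float
    components: tuple[float, ...]

    @property
    def E(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class NeighborSet:
    """The E+1 nearest library vectors of one prediction vector."""

    neighbor_times: np.ndarray
    distances: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be non-decreasing")
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class ReconstructedAttractor:
    """A regime's library of delay vectors plus its embedding dimension.

    ``vectors`` has one row per library vector (ascending anchor order, which
    the neighbor search relies on for deterministic tie-breaking), and
    ``values`` retains the full source series so that successor observations
    Y(t_m + 1) and contemporaneous responses remain addressable.
    """

    vectors: np.ndarray
    anchor_idx: np.ndarray
    values: np.ndarray
    times: np.ndarray
    E: int
    source_regime: str = ""
    source_variable: str = ""
    cv_skill: float = float("nan")

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.values) - self.E + 1, self.E):
            raise ValueError("library size must equal n - E + 1")

    @property
    def library_size(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class ForecastResult:
    """Aligned observed/predicted values with their provenance."""

    target_times: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    library_regime: str
    target_regime: str
    mode: str
    E_used: int

    def __post_init__(self) -> None:
        if not (len(self.target_times) == len(self.observed) == len(self.predicted)):
            raise ValueError("observed and predicted must be aligned")
        if len(self.observed) < 1:
            raise ValueError("a forecast must contain at least one prediction")

    def __len__(self) -> int:
        return len(self.observed)

    @property
    def is_within(self) -> bool:
        return self.library_regime == self.target_regime

    def pearson(self) -> float:
        """Pearson correlation between observations and predictions."""
        return float(np.corrcoef(self.observed, self.predicted)[0, 1])


# ---------------------------------------------------------------------------
# embedding


def _values_of(series) -> np.ndarray:
    if isinstance(series, RegimeSeries):
        x = series.values
    else:
        x = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series values must be finite")
    return x


def embed_array(values: np.ndarray, E: int) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embed a 1-D array with lag 1.

    Returns ``(vectors, anchor_idx)`` where row i of ``vectors`` is
    ``< y(t), y(t-1), ..., y(t-(E-1)) >`` anchored at positional index
    ``anchor_idx[i]``.  Exactly ``n - E + 1`` vectors are produced.
    """
    x = _values_of(values)
    n = len(x)
    if E < 1:
        raise ValueError("embedding dimension must be >= 1")
    if E > n:
        raise InsufficientDataError(
            f"cannot build E={E} vectors from a length-{n} series"
        )
    anchors = np.arange(E - 1, n)
    vectors = np.column_stack([x[anchors - k] for k in range(E)])
    return vectors, anchors


def embed(series: RegimeSeries, E: int) -> list[DelayVector]:
    """Delay-embed a series, returning explicit :class:`DelayVector` objects."""
    vectors, anchors = embed_array(series, E)
    times = series.times if isinstance(series, RegimeSeries) else np.arange(len(vectors) + E - 1)
    return [
        DelayVector(anchor_time=float(times[a]), components=tuple(v))
        for v, a in zip(vectors, anchors)
    ]


def neighbor_weights(distances: Sequence[float]) -> np.ndarray:
    """Exponential simplex weights w_m = u_m / sum(u), u_m = exp(-d_m/d_1).

    ``distances`` must be the sorted (ascending) distances to the E+1 nearest
    neighbors.  If the nearest distance is exactly zero the formula is
    undefined; its continuity limit assigns equal weight to every
    zero-distance neighbor and zero elsewhere.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("at least one neighbor distance is required")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if d[0] == 0.0:
        w = (d == 0.0).astype(float)
        return w / w.sum()
    with np.errstate(over="ignore"):
        # d/d[0] may overflow to inf for a near-zero nearest distance;
        # exp(-inf) = 0 is the correct limit.
        u = np.exp(-d / d[0])
    return u / u.sum()


# ---------------------------------------------------------------------------
# neighbor search and the simplex kernel


def _distance_matrix(queries: np.ndarray, library: np.ndarray) -> np.ndarray:
    # Explicit difference/sum form: the summation order over components
    # matches the exhaustive reference implementation exactly.
    diff = queries[:, None, :] - library[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def _knn_predict(
    library_vectors: np.ndarray,
    library_anchor_idx: np.ndarray,
    library_targets: np.ndarray,
    query_vectors: np.ndarray,
    query_anchor_idx: np.ndarray,
    E: int,
    exclude_self: bool,
    theiler: int = 0,
) -> np.ndarray:
    """Simplex kernel: weighted average of targets over E+1 nearest neighbors.

    ``library_targets[i]`` is the value contributed by library vector i (the
    successor observation in univariate mode, the contemporaneous response in
    cross-map mode).  When ``exclude_self`` is set, library vectors whose
    anchor lies within ``theiler`` steps of the query anchor are ineligible
    (theiler = 0 excludes only the identical anchor).
    """
    k = E + 1
    D = _distance_matrix(query_vectors, library_vectors)
    preds = np.empty(len(query_vectors))
    for i in range(len(query_vectors)):
        d = D[i]
        if exclude_self:
            eligible = np.abs(library_anchor_idx - query_anchor_idx[i]) > theiler
            if eligible.sum() < k:
                raise InsufficientDataError(
                    f"only {int(eligible.sum())} eligible neighbors after "
                    f"self-exclusion; {k} required"
                )
            idx = np.flatnonzero(eligible)
        else:
            if len(d) < k:
                raise InsufficientDataError(
                    f"library holds {len(d)} vectors; {k} neighbors required"
                )
            idx = np.arange(len(d))
        # Stable sort on distance; the library is in ascending anchor order,
        # so ties at the (E+1)-th neighbor resolve to the smaller anchor time.
        order = idx[np.argsort(d[idx], kind="stable")[:k]]
        w = neighbor_weights(d[order])
        preds[i] = float(w @ library_targets[order])
    return preds


# ---------------------------------------------------------------------------
# embedding-dimension selection


def _loo_skill(x: np.ndarray, E: int, theiler: int = 0) -> float:
    """Leave-one-out one-step simplex skill (Pearson r) of a series at one E.

    Returns NaN when the correlation is undefined (constant predictions or
    constant observations).
    """
    vectors, anchors = embed_array(x, E)
    has_successor = anchors < len(x) - 1
    lib_vec = vectors[has_successor]
    lib_anchor = anchors[has_successor]
    succ = x[lib_anchor + 1]
    if len(lib_vec) - 1 < E + 1:
        raise InsufficientDataError(
            f"series of length {len(x)} too short for E={E} leave-one-out forecasts"
        )
    preds = _knn_predict(
        lib_vec, lib_anchor, succ, lib_vec, lib_anchor, E,
        exclude_self=True, theiler=theiler,
    )
    obs = succ
    if np.std(preds) == 0.0 or np.std(obs) == 0.0:
        return float("nan")
    return float(np.corrcoef(obs, preds)[0, 1])


def default_e_max(n: int) -> int:
    """Default search ceiling for E: min(10, floor(n/2) - 1)."""
    return min(DEFAULT_E_CEILING, n // 2 - 1)


def select_embedding_dimension(
    series,
    E_max: int | None = None,
    theiler: int = 0,
) -> ReconstructedAttractor:
    """Reconstruct a regime's attractor at the cross-validated best E.

    For each E in 1..E_max the series forecasts itself one step ahead with
    the self vector excluded, and the Pearson correlation between observed
    and predicted values is the skill.  The smallest E attaining the maximum
    wins; its library of delay vectors is the reconstructed attractor.
    """
    x = _values_of(series)
    n = len(x)
    if E_max is None:
        E_max = default_e_max(n)
    if E_max < 1:
        raise InsufficientDataError(
            f"series of length {n} too short for any embedding"
        )
    if n < E_max + 2:
        raise InsufficientDataError(
            f"series of length {n} too short for E_max={E_max} "
            f"(need at least E_max + 2 points)"
        )
    best_E, best_r = None, -np.inf
    for E in range(1, E_max + 1):
        r = _loo_skill(x, E, theiler=theiler)
        if np.isfinite(r) and r > best_r:
            best_E, best_r = E, r
    label = series.regime_label if isinstance(series, RegimeSeries) else ""
    var = series.variable_name if isinstance(series, RegimeSeries) else ""
    if best_E is None:
        raise DegenerateSeriesError(
            f"forecast skill undefined at every E for regime {label!r} "
            f"(variable {var!r}); the series carries no usable signal"
        )
    vectors, anchors = embed_array(x, best_E)
    times = series.times if isinstance(series, RegimeSeries) else np.arange(n, dtype=float)
    return ReconstructedAttractor(
        vectors=vectors,
        anchor_idx=anchors,
        values=x,
        times=np.asarray(times, dtype=float),
        E=best_E,
        source_regime=label,
        source_variable=var,
        cv_skill=best_r,
    )


# ---------------------------------------------------------------------------
# estimators


class SimplexForecaster(BaseEstimator):
    """Univariate simplex-projection forecaster (scikit-learn style).

    Parameters
    ----------
    embedding_dim : int or None
        Fixed embedding dimension E.  When None (default) E is selected on
        the library series by leave-one-out forecast skill.
    max_embedding_dim : int or None
        Search ceiling for the automatic selection; defaults to
        ``min(10, n // 2 - 1)``.
    theiler : int
        Temporal exclusion radius around the predicted time when
        ``exclude_self`` forecasting is requested.  0 (default) excludes only
        the vector anchored at the predicted time itself.

    Attributes
    ----------
    attractor_ : ReconstructedAttractor
        The fitted library.
    embedding_dim_ : int
        The embedding dimension in use.
    cv_skill_ : float
        Leave-one-out Pearson skill of the library at ``embedding_dim_``.
    """

    def __init__(self, embedding_dim=None, max_embedding_dim=None, theiler=0):
        self.embedding_dim = embedding_dim
        self.max_embedding_dim = max_embedding_dim
        self.theiler = theiler

    def fit(self, X, y=None):
        """Build the library from a univariate series (RegimeSeries or 1-D array)."""
        if self.embedding_dim is None:
            self.attractor_ = select_embedding_dimension(
                X, E_max=self.max_embedding_dim, theiler=self.theiler
            )
        else:
            x = _values_of(X)
            vectors, anchors = embed_array(x, self.embedding_dim)
            times = (
                X.times if isinstance(X, RegimeSeries)
                else np.arange(len(x), dtype=float)
            )
            label = X.regime_label if isinstance(X, RegimeSeries) else ""
            var = X.variable_name if isinstance(X, RegimeSeries) else ""
            try:
                skill = _loo_skill(x, self.embedding_dim, theiler=self.theiler)
            except InsufficientDataError:
                skill = float("nan")
            self.attractor_ = ReconstructedAttractor(
                vectors=vectors, anchor_idx=anchors, values=x,
                times=np.asarray(times, dtype=float), E=self.embedding_dim,
                source_regime=label, source_variable=var, cv_skill=skill,
            )
        self.embedding_dim_ = self.attractor_.E
        self.cv_skill_ = self.attractor_.cv_skill
        return self

    def _check_fitted(self):
        if not hasattr(self, "attractor_"):
            raise RuntimeError("forecaster is not fitted; call fit() first")

    def predict(self, X, exclude_self: bool = False) -> np.ndarray:
        """One-step-ahead forecasts of a target series from the fitted library.

        Target vectors are built with the *library's* E.  Set
        ``exclude_self=True`` when the target is the library series itself
        (within-regime prediction), so the zero-distance self-match cannot
        absorb all weight.
        """
        return self.forecast(X, exclude_self=exclude_self).predicted

    def forecast(self, X, exclude_self: bool = False) -> ForecastResult:
        """As :meth:`predict`, but returns the full :class:`ForecastResult`."""
        self._check_fitted()
        att = self.attractor_
        x = _values_of(X)
        E = att.E
        lib_has_succ = att.anchor_idx < len(att.values) - 1
        lib_vec = att.vectors[lib_has_succ]
        lib_anchor = att.anchor_idx[lib_has_succ]
        succ = att.values[lib_anchor + 1]
        if len(lib_vec) == 0:
            raise InsufficientDataError("no library vector has a successor")
        q_vec, q_anchor = embed_array(x, E)
        has_succ = q_anchor < len(x) - 1
        q_vec, q_anchor = q_vec[has_succ], q_anchor[has_succ]
        if len(q_vec) == 0:
            raise InsufficientDataError("target series too short to forecast")
        preds = _knn_predict(
            lib_vec, lib_anchor, succ, q_vec, q_anchor, E,
            exclude_self=exclude_self, theiler=self.theiler,
        )
        times = (
            X.times if isinstance(X, RegimeSeries)
            else np.arange(len(x), dtype=float)
        )
        target_label = X.regime_label if isinstance(X, RegimeSeries) else ""
        return ForecastResult(
            target_times=np.asarray(times, dtype=float)[q_anchor + 1],
            observed=x[q_anchor + 1],
            predicted=preds,
            library_regime=att.source_regime,
            target_regime=target_label,
            mode="univariate",
            E_used=E,
        )

    def score(self, X, y=None) -> float:
        """Pearson correlation of one-step self-excluded forecasts of X."""
        return self.forecast(X, exclude_self=True).pearson()


class CrossMapForecaster(BaseEstimator):
    """Cross-map forecaster: the embedding of X predicts contemporaneous Y.

    fit(X, y) embeds the predictor series X (E chosen by X's own univariate
    leave-one-out skill) and stores the aligned response series y; predict
    maps a target regime's X-vectors onto the library's response values at
    the neighbor times (no +1 shift).  Since the predicted variable never
    enters the library geometry, neither within- nor across-regime cross-map
    predictions are made on data used to fit the model.
    """

    def __init__(self, embedding_dim=None, max_embedding_dim=None, theiler=0):
        self.embedding_dim = embedding_dim
        self.max_embedding_dim = max_embedding_dim
        self.theiler = theiler

    def fit(self, X, y):
        x = _values_of(X)
        yv = _values_of(y)
        if len(x) != len(yv):
            raise ValueError("predictor and response series must be aligned")
        base = SimplexForecaster(
            embedding_dim=self.embedding_dim,
            max_embedding_dim=self.max_embedding_dim,
            theiler=self.theiler,
        ).fit(X)
        self.attractor_ = base.attractor_
        self.embedding_dim_ = base.embedding_dim_
        self.cv_skill_ = base.cv_skill_
        self.response_ = yv
        self.response_name_ = (
            y.variable_name if isinstance(y, RegimeSeries) else ""
        )
        return self

    def predict(self, X, exclude_self: bool = False) -> np.ndarray:
        return self.forecast(X, None, exclude_self=exclude_self).predicted

    def forecast(self, X, y=None, exclude_self: bool = False) -> ForecastResult:
        """Cross-map a target regime's X onto the library's response values.

        When ``y`` (the target regime's observed response) is given, the
        result pairs predictions with those observations; otherwise observed
        is filled with NaN and only ``predicted`` is meaningful.
        """
        if not hasattr(self, "attractor_"):
            raise RuntimeError("forecaster is not fitted; call fit() first")
        att = self.attractor_
        x = _values_of(X)
        E = att.E
        q_vec, q_anchor = embed_array(x, E)
        preds = _knn_predict(
            att.vectors, att.anchor_idx, self.response_[att.anchor_idx],
            q_vec, q_anchor, E,
            exclude_self=exclude_self, theiler=self.theiler,
        )
        times = (
            X.times if isinstance(X, RegimeSeries)
            else np.arange(len(x), dtype=float)
        )
        if y is not None:
            yv = _values_of(y)
            if len(yv) != len(x):
                raise ValueError("target X and Y series must be aligned")
            observed = yv[q_anchor]
        else:
            observed = np.full(len(q_anchor), np.nan)
        target_label = X.regime_label if isinstance(X, RegimeSeries) else ""
        return ForecastResult(
            target_times=np.asarray(times, dtype=float)[q_anchor],
            observed=observed,
            predicted=preds,
            library_regime=att.source_regime,
            target_regime=target_label,
            mode="multivariate",
            E_used=E,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def simplex_forecast(
    target,
    library_attractor: ReconstructedAttractor,
    self_exclusion: bool = False,
    theiler: int = 0,
) -> ForecastResult:
    """One-step simplex forecast of ``target`` from a prebuilt library."""
    f = SimplexForecaster(embedding_dim=library_attractor.E, theiler=theiler)
    f.attractor_ = library_attractor
    f.embedding_dim_ = library_attractor.E
    f.cv_skill_ = library_attractor.cv_skill
    return f.forecast(target, exclude_self=self_exclusion)


def cross_map_forecast(
    target_X,
    target_Y,
    library_X_attractor: ReconstructedAttractor,
    library_Y,
    self_exclusion: bool = False,
    theiler: int = 0,
) -> ForecastResult:
    """Cross-map forecast of target_Y from the library regime's X-embedding."""
    f = CrossMapForecaster(embedding_dim=library_X_attractor.E, theiler=theiler)
    f.attractor_ = library_X_attractor
    f.embedding_dim_ = library_X_attractor.E
    f.cv_skill_ = library_X_attractor.cv_skill
    yv = _values_of(library_Y)
    if len(yv) != len(library_X_attractor.values):
        raise ValueError("library X and Y series must be aligned")
    f.response_ = yv
    f.response_name_ = (
        library_Y.variable_name if isinstance(library_Y, RegimeSeries) else ""
    )
    return f.forecast(target_X, target_Y, exclude_self=self_exclusion)
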
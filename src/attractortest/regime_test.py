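"""The attractor-difference test.

If two segments of a time series are governed by the same attractor, a
library built from either segment should forecast the other about as well as
it forecasts itself.  The test therefore compares the mean absolute
prediction error of across-regime forecasts (MAPE_A) with that of
within-regime forecasts (MAPE_W) and asks, one-sidedly, whether

    D = MAPE_A - MAPE_W

is larger than expected under exchangeable errors.  Absolute (not squared)
errors damp the influence of the skewed extremes that simplex forecasts of
cyclic data produce, and because the errors are far from normal the null
distribution is built by permutation: all errors are pooled and randomly
re-dealt into two groups of the original sizes.  Significance at the 95th
percentile of the permuted differences corresponds to p <= 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from . import edm
from .config import RunConfig
from .exceptions import AttractorTestError
from .series import RegimePair, RegimeSeries, standardize

__all__ = [
    "PredictionErrorSet",
    "RegimeTestResult",
    "absolute_errors",
    "mape",
    "permutation_test",
    "directional_regime_test",
    "full_regime_test",
]

#: Child-stream tag so permutation draws never collide with simulator noise
#: when everything flows from one experiment seed.
_PERMUTATION_STREAM = 0x5EED


@dataclass(frozen=True)
class PredictionErrorSet:
    """Absolute prediction errors labeled by forecast direction."""

    absolute_errors: np.ndarray
    direction_label: str  # "within" | "across"
    target_regime: str = ""
    library_regime: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.absolute_errors, dtype=float)
        object.__setattr__(self, "absolute_errors", e)
        if e.size and (np.any(e < 0) or not np.all(np.isfinite(e))):
            raise ValueError("absolute errors must be finite and non-negative")
        if self.direction_label not in ("within", "across"):
            raise ValueError("direction_label must be 'within' or 'across'")

    def __len__(self) -> int:
        return len(self.absolute_errors)


@dataclass(frozen=True)
class RegimeTestResult:
    """Everything one directional test computed, with its configuration."""

    mape_within: float
    mape_across: float
    p_value: float
    n_within: int
    n_across: int
    n_permutations: int
    seed: int | None
    alpha: float
    significant: bool
    mode: str
    E_within: int
    E_across: int
    target_regime: str = ""
    library_regime: str = ""

    @property
    def observed_difference(self) -> float:
        return self.mape_across - self.mape_within

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["observed_difference"] = self.observed_difference
        return d


def absolute_errors(forecast: edm.ForecastResult) -> PredictionErrorSet:
    """Elementwise |predicted - observed|, labeled within/across."""
    if len(forecast) == 0:
        raise ValueError("forecast is empty")
    return PredictionErrorSet(
        absolute_errors=np.abs(forecast.predicted - forecast.observed),
        direction_label="within" if forecast.is_within else "across",
        target_regime=forecast.target_regime,
        library_regime=forecast.library_regime,
    )


def mape(errors) -> float:
    """Arithmetic mean of a set of absolute prediction errors."""
    e = errors.absolute_errors if isinstance(errors, PredictionErrorSet) else np.asarray(errors, float)
    if e.size == 0:
        raise ValueError("cannot average an empty error set")
    return float(np.mean(e))


def _as_error_array(errors) -> np.ndarray:
    if isinstance(errors, PredictionErrorSet):
        return errors.absolute_errors
    return np.asarray(errors, dtype=float)


def permutation_test(
    across,
    within,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "auto",
) -> tuple[float, float]:
    """One-sided permutation test of D = mean(across) - mean(within).

    The pooled errors are re-dealt into two groups of the original sizes and
    D recomputed for each re-dealing.  The p-value is the (add-one smoothed)
    fraction of permuted differences at least as large as the observed one:

        p = (1 + #{D_perm >= D_obs}) / (1 + n_permutations).

    When the number of distinct group assignments C(n, n_across) does not
    exceed ``n_permutations`` (always the case for total sizes <= 12 at the
    default 1000) the test enumerates them all, so the Monte-Carlo p-value
    coincides with the exact one.  Returns ``(p_value, observed_difference)``.
    """
    a = _as_error_array(across)
    w = _as_error_array(within)
    if a.size == 0 or w.size == 0:
        raise ValueError("both error sets must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d_obs = float(np.mean(a) - np.mean(w))
    pooled = np.concatenate([a, w])
    n, n_a = len(pooled), len(a)
    if np.ptp(pooled) == 0.0:
        warnings.warn(
            "all pooled errors are identical; the permutation null is "
            "degenerate and p is reported as 1",
            RuntimeWarning,
        )
        return 1.0, d_obs
    eps = 1e-12 * max(1.0, abs(d_obs))
    total_sum = float(pooled.sum())

    def diff_from_sum_a(sum_a):
        return sum_a / n_a - (total_sum - sum_a) / (n - n_a)

    n_exact = math.comb(n, n_a)
    if method == "exact" or (method == "auto" and n_exact <= n_permutations):
        hits = 0
        for combo in combinations(range(n), n_a):
            if diff_from_sum_a(float(pooled[list(combo)].sum())) >= d_obs - eps:
                hits += 1
        # The observed assignment is one of the enumerated ones, so the
        # add-one form with n_permutations = n_exact - 1 is the exact p.
        return hits / n_exact, d_obs
    if method not in ("auto", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    # Vectorized label shuffle: each row of random keys induces one re-dealing.
    keys = rng.random((n_permutations, n))
    take = np.argsort(keys, axis=1)[:, :n_a]
    sums_a = pooled[take].sum(axis=1)
    d_perm = diff_from_sum_a(sums_a)
    hits = int(np.sum(d_perm >= d_obs - eps))
    return (1 + hits) / (1 + n_permutations), d_obs


# ---------------------------------------------------------------------------
# the directional test


def _maybe_standardize(series: RegimeSeries, config: RunConfig) -> RegimeSeries:
    if config.standardize and not series.standardized:
        return standardize(series)
    return series


def _resolve_config(config: RunConfig | None, overrides) -> RunConfig:
    cfg = config if config is not None else RunConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _permutation_rng(cfg: RunConfig) -> np.random.Generator:
    if cfg.seed is None:
        return np.random.default_rng()
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), _PERMUTATION_STREAM])
    )


def _univariate_errors(target, within_library, across_library, cfg):
    t = _maybe_standardize(target, cfg)
    wlib = _maybe_standardize(within_library, cfg)
    alib = _maybe_standardize(across_library, cfg)
    att_w = edm.select_embedding_dimension(wlib, E_max=cfg.e_max, theiler=cfg.theiler)
    att_a = edm.select_embedding_dimension(alib, E_max=cfg.e_max, theiler=cfg.theiler)
    f_w = edm.simplex_forecast(
        t, att_w, self_exclusion=cfg.self_exclusion, theiler=cfg.theiler
    )
    f_a = edm.simplex_forecast(t, att_a, self_exclusion=False, theiler=cfg.theiler)
    # Directions follow the library's *role*, not its label: on a diagonal
    # cell the across library is an independent draw of the same regime.
    err_w = PredictionErrorSet(
        np.abs(f_w.predicted - f_w.observed), "within",
        target_regime=t.regime_label, library_regime=wlib.regime_label,
    )
    err_a = PredictionErrorSet(
        np.abs(f_a.predicted - f_a.observed), "across",
        target_regime=t.regime_label, library_regime=alib.regime_label,
    )
    return err_w, err_a, att_w.E, att_a.E


def _multivariate_errors(target, within_library, across_library, cfg):
    predictor = cfg.predictor
    if predictor is None:
        raise ValueError("multivariate mode requires config.predictor")
    responses = cfg.responses
    if responses is None:
        responses = tuple(v for v in sorted(target) if v != predictor)
    if not responses:
        raise ValueError("multivariate mode requires at least one response variable")

    def prep(bundle):
        return {v: _maybe_standardize(bundle[v], cfg) for v in bundle}

    t, wlib, alib = prep(target), prep(within_library), prep(across_library)
    att_w = edm.select_embedding_dimension(
        wlib[predictor], E_max=cfg.e_max, theiler=cfg.theiler
    )
    att_a = edm.select_embedding_dimension(
        alib[predictor], E_max=cfg.e_max, theiler=cfg.theiler
    )
    errs_w, errs_a = [], []
    for r in responses:
        f_w = edm.cross_map_forecast(
            t[predictor], t[r], att_w, wlib[r],
            self_exclusion=cfg.self_exclusion, theiler=cfg.theiler,
        )
        f_a = edm.cross_map_forecast(
            t[predictor], t[r], att_a, alib[r],
            self_exclusion=False, theiler=cfg.theiler,
        )
        errs_w.append(absolute_errors(f_w).absolute_errors)
        errs_a.append(absolute_errors(f_a).absolute_errors)
    first = next(iter(t.values()))
    w_set = PredictionErrorSet(
        np.concatenate(errs_w), "within",
        target_regime=first.regime_label, library_regime=first.regime_label,
    )
    first_a = next(iter(alib.values()))
    a_set = PredictionErrorSet(
        np.concatenate(errs_a), "across",
        target_regime=first.regime_label, library_regime=first_a.regime_label,
    )
    return w_set, a_set, att_w.E, att_a.E


def directional_regime_test(
    target,
    within_library,
    across_library,
    mode: str = "univariate",
    config: RunConfig | None = None,
    **overrides,
) -> RegimeTestResult:
    """Test one direction: can regime j's library predict regime i's data?

    ``target`` is regime i's data (a :class:`RegimeSeries`, or for the
    multivariate mode a mapping of variable name to series);
    ``within_library`` is regime i's own data (usually the same object) and
    ``across_library`` regime j's.  Within-regime forecasts exclude the
    library vector anchored at the predicted time so a zero-distance
    self-match cannot trivialize them.  A significant result means the
    across-regime errors exceed the within-regime errors beyond the
    permutation null — regime i's dynamics are not reproduced by regime j's
    attractor.
    """
    cfg = _resolve_config(config, overrides)
    try:
        if mode == "univariate":
            err_w, err_a, e_w, e_a = _univariate_errors(
                target, within_library, across_library, cfg
            )
        elif mode == "multivariate":
            err_w, err_a, e_w, e_a = _multivariate_errors(
                target, within_library, across_library, cfg
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except AttractorTestError as exc:
        raise type(exc)(
            f"{exc} [target regime {err_context(target)!r}]"
        ) from exc
    p, _ = permutation_test(
        err_a, err_w,
        n_permutations=cfg.n_permutations,
        rng=_permutation_rng(cfg),
    )
    return RegimeTestResult(
        mape_within=mape(err_w),
        mape_across=mape(err_a),
        p_value=p,
        n_within=len(err_w),
        n_across=len(err_a),
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
        alpha=cfg.alpha,
        significant=p <= cfg.alpha,
        mode=mode,
        E_within=e_w,
        E_across=e_a,
        target_regime=err_w.target_regime,
        library_regime=err_a.library_regime,
    )


def err_context(target) -> str:
    if isinstance(target, RegimeSeries):
        return target.regime_label
    try:
        return next(iter(target.values())).regime_label
    except Exception:
        return "?"


def full_regime_test(
    pair: RegimePair,
    mode: str = "univariate",
    config: RunConfig | None = None,
    **overrides,
) -> tuple[RegimeTestResult, RegimeTestResult]:
    """Run both directions of the test on a pair of regimes.

    Returns ``(result_a, result_b)`` where ``result_a`` targets regime A
    (library from B) and ``result_b`` targets regime B (library from A).
    """
    res_a = directional_regime_test(
        pair.regime_a, pair.regime_a, pair.regime_b, mode=mode,
        config=config, **overrides,
    )
    res_b = directional_regime_test(
        pair.regime_b, pair.regime_b, pair.regime_a, mode=mode,
        config=config, **overrides,
    )
    return res_a, res_b
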
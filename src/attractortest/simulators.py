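"""Synthetic regime generators: chaotic food chain and stochastic bistability.

Two models generate the study conditions under which the attractor test is
characterized.

**Tri-trophic food chain.**  The resource-consumer-predator system

    dR/dt = R (1 - R/K) - x_c y_c C R / (R + R0)
    dC/dt = x_c C (-1 + y_c R / (R + R0)) - x_p y_p P C / (C + C0)
    dP/dt = x_p P (-1 + y_p C / (C + C0))

with bioenergetic rates x_c = 0.4, y_c = 2.009, x_p = 0.08, y_p = 2.876 and
half-saturation constants R0 = 0.16129, C0 = 0.5.  Sweeping the resource
carrying capacity K walks the system through a period-doubling cascade:
K = 0.78 equilibrium, K = 0.85 two-point limit cycle, K = 0.92 four-point
limit cycle, K = 0.997 chaos.  Trajectories are integrated adaptively,
burned in, output at unit time steps, subsampled (every fifth point by
default, about 10 samples per cycle of the two-point regime) and finally
corrupted with multiplicative-scaled observation noise

    N(t) = N'(t) + rho * e(t),   e(t) ~ Normal(0, sd(N')),

where sd(N') is the standard deviation of the species' own deterministic
sampled trajectory.

**Stochastic alternative stable states.**  A one-dimensional grazing model

    dx = [ x (1 - x/K) - c x^2 / (1 + x^2) ] dt + sigma dW,

with K = 11, sigma = 0.01 and harvest rate c.  Between the two saddle-node
folds of the noise-free skeleton the model is bistable; paths are started on
the equilibrium of the chosen branch and sigma is kept small so they do not
flicker between basins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import (
    BistabilityError,
    DegenerateSeriesError,
    InsufficientDataError,
    SimulationError,
)
from .series import RegimeSeries

__all__ = [
    "FoodChainParams",
    "ASSParams",
    "simulate_food_chain",
    "sample_series",
    "add_observation_noise",
    "classify_food_chain_regime",
    "estimate_cycle_period",
    "simulate_ass",
    "skeleton_equilibria",
    "find_fold_points",
    "ass_drift",
]


# ---------------------------------------------------------------------------
# food chain


@dataclass(frozen=True)
class FoodChainParams:
    """Parameters of the tri-trophic food chain (bioenergetic defaults)."""

    K: float
    x_c: float = 0.4
    y_c: float = 2.009
    x_p: float = 0.08
    y_p: float = 2.876
    R0: float = 0.16129
    C0: float = 0.5
    r: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")


def _food_chain_rhs(t, state, p: FoodChainParams):
    R, C, P = state
    fRC = p.x_c * p.y_c * C * R / (R + p.R0)
    fCP = p.x_p * p.y_p * P * C / (C + p.C0)
    dR = p.r * R * (1 - R / p.K) - fRC
    dC = p.x_c * C * (-1 + p.y_c * R / (R + p.R0)) - fCP
    dP = p.x_p * P * (-1 + p.y_p * C / (C + p.C0))
    return (dR, dC, dP)


def simulate_food_chain(
    params: FoodChainParams,
    total_time: float = 11500.0,
    burn_in: float = 10000.0,
    output_step: float = 1.0,
    initial_state=(0.8, 0.2, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, RegimeSeries]:
    """Integrate the food chain and return post-burn-in trajectories.

    Integration is adaptive Runge-Kutta at tight tolerance; the burn-in is
    discarded and the trajectory is reported every ``output_step`` time
    units, re-based to start at time 0.  Deterministic.

    The defaults matter.  The model is bistable between the three-species
    coexistence attractor and a predator-free resource-consumer cycle; the
    default initial state lies in the coexistence basin for all four study
    carrying capacities (symmetric starts such as (0.5, 0.5, 0.5) lose the
    predator for K >= 0.85).  The default burn-in of 10000 time units is set
    by the slowest case, the period-doubled cycle at K = 0.92, whose
    transient outlasts several thousand time units.
    """
    if total_time <= burn_in:
        raise ValueError("total_time must exceed burn_in")
    if any(v <= 0 for v in initial_state):
        raise ValueError("initial densities must be positive")
    t_eval = np.arange(burn_in, total_time + 0.5 * output_step, output_step)
    sol = solve_ivp(
        _food_chain_rhs,
        (0.0, float(t_eval[-1])),
        np.asarray(initial_state, dtype=float),
        t_eval=t_eval,
        args=(params,),
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("non-finite state in food-chain trajectory")
    times = sol.t - burn_in
    label = f"K={params.K:g}"
    return {
        name: RegimeSeries(sol.y[i], times, regime_label=label, variable_name=name)
        for i, name in enumerate(("R", "C", "P"))
    }


def sample_series(series: RegimeSeries, every: int = 5) -> RegimeSeries:
    """Keep every ``every``-th observation (indices 0, every, 2*every, ...)."""
    if every < 1:
        raise ValueError("every must be >= 1")
    return RegimeSeries(
        series.values[::every],
        series.times[::every],
        regime_label=series.regime_label,
        variable_name=series.variable_name,
        standardized=False,
    )


def add_observation_noise(
    series: RegimeSeries,
    rho: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegimeSeries:
    """Add observation noise scaled to the deterministic series' own sd.

    The noise sd is ``rho * sd(series)`` with the sample (n-1) denominator,
    so rho is a dimensionless noise-to-signal level.  Seeded and
    reproducible.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if rho == 0:
        return series.with_values(series.values.copy())
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError(
            "cannot scale observation noise to a zero-variance series"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = series.values + rho * sd * rng.standard_normal(len(series))
    return series.with_values(noisy)


def _refined_peak_heights(x: np.ndarray) -> np.ndarray:
    """Local-maximum values with parabolic refinement through each peak."""
    left, mid, right = x[:-2], x[1:-1], x[2:]
    is_peak = (mid >= left) & (mid > right)
    idx = np.flatnonzero(is_peak) + 1
    heights = np.empty(len(idx))
    for j, i in enumerate(idx):
        a, b, c = x[i - 1], x[i], x[i + 1]
        denom = a - 2 * b + c
        if denom < 0:  # proper quadratic maximum
            heights[j] = b - (a - c) ** 2 / (8 * denom)
        else:
            heights[j] = b
    return heights


def _cluster_1d(sorted_values: np.ndarray, tol: float) -> np.ndarray:
    """Greedy gap clustering of sorted values; returns cluster id per value."""
    ids = np.zeros(len(sorted_values), dtype=int)
    for i in range(1, len(sorted_values)):
        gap = sorted_values[i] - sorted_values[i - 1]
        ids[i] = ids[i - 1] + (1 if gap > tol else 0)
    return ids


def _extremum_clusters(z: np.ndarray, tol: float):
    """Cluster the local-maximum heights of z; returns (k, labels_in_order)."""
    heights = _refined_peak_heights(z)
    if len(heights) == 0:
        return 0, np.empty(0, dtype=int)
    order = np.argsort(heights, kind="stable")
    ids_sorted = _cluster_1d(heights[order], tol)
    labels = np.empty(len(heights), dtype=int)
    labels[order] = ids_sorted
    return int(ids_sorted[-1]) + 1, labels


def classify_food_chain_regime(
    series: RegimeSeries,
    equilibrium_tol: float = 1e-4,
    cluster_rtol: float = 1e-3,
    max_points: int = 8,
) -> str:
    """Label a deterministic post-burn-in trajectory by its attractor type.

    A flat series (range below ``equilibrium_tol``) is an equilibrium.
    Otherwise the series is standardized and its local extrema are clustered
    by level with relative tolerance ``cluster_rtol``; the number of
    distinct extremum levels — maximum clusters plus minimum clusters —
    names the cycle in the "n-point" convention of discrete population
    dynamics.  A simple limit cycle (one maximum level, one minimum level)
    is ``cycle_2``; its first period-doubling, which splits both levels, is
    ``cycle_4``.  If the extrema do not settle into at most ``max_points``
    levels visited in a fixed rotation, the trajectory is ``aperiodic``.
    """
    x = series.values
    if np.ptp(x) < equilibrium_tol:
        return "equilibrium"
    z = (x - np.mean(x)) / np.std(x, ddof=1)
    tol = cluster_rtol * float(np.ptp(z))
    k_max, labels_max = _extremum_clusters(z, tol)
    k_min, labels_min = _extremum_clusters(-z, tol)
    if min(len(labels_max), len(labels_min)) < 8:
        raise InsufficientDataError(
            f"only {len(labels_max)} maxima / {len(labels_min)} minima "
            "found; at least 8 of each are needed to classify a "
            "non-equilibrium regime"
        )
    k = k_max + k_min
    if k > max_points:
        return "aperiodic"
    # A limit cycle visits its extremum levels in a fixed rotation.
    for kk, labels in ((k_max, labels_max), (k_min, labels_min)):
        if kk > 1 and not np.all(labels[:-kk] == labels[kk:]):
            return "aperiodic"
    return f"cycle_{k}"


def estimate_cycle_period(series: RegimeSeries, cluster_rtol: float = 1e-3) -> float:
    """Full period of a limit cycle from the recurrence of its maxima.

    The mean spacing of successive local maxima, multiplied by the number of
    distinct maximum levels, is the time for the cycle to revisit the same
    peak — the full period even after period-doubling.
    """
    x = series.values
    z = (x - np.mean(x)) / np.std(x, ddof=1)
    left, mid, right = z[:-2], z[1:-1], z[2:]
    idx = np.flatnonzero((mid >= left) & (mid > right)) + 1
    if len(idx) < 3:
        raise InsufficientDataError("too few maxima to estimate a period")
    tol = cluster_rtol * float(np.ptp(z))
    k_max, _ = _extremum_clusters(z, tol)
    spacing = float(np.mean(np.diff(series.times[idx])))
    return k_max * spacing


# ---------------------------------------------------------------------------
# alternative stable states


@dataclass(frozen=True)
class ASSParams:
    """Parameters of the stochastic grazing model."""

    c: float
    K: float = 11.0
    sigma: float = 0.01
    dt: float = 0.01
    branch: str = "lower"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K <= 0 or self.dt <= 0 or self.sigma < 0 or self.c < 0:
            raise ValueError("require K > 0, dt > 0, sigma >= 0, c >= 0")
        if self.branch not in ("lower", "upper"):
            raise ValueError("branch must be 'lower' or 'upper'")


def ass_drift(x, c: float, K: float = 11.0):
    """Noise-free skeleton drift x(1 - x/K) - c x^2 / (1 + x^2)."""
    x = np.asarray(x, dtype=float)
    return x * (1 - x / K) - c * x * x / (1 + x * x)


def _ass_drift_derivative(x: float, c: float, K: float) -> float:
    return 1 - 2 * x / K - 2 * c * x / (1 + x * x) ** 2


def skeleton_equilibria(c: float, K: float = 11.0) -> list[tuple[float, str]]:
    """All non-negative equilibria of the skeleton, tagged by stability.

    Non-zero equilibria are the positive real roots of the cubic
    ``x^3 - K x^2 + (1 + cK) x - K = 0``; each root is polished by bisection
    to 1e-9 and tagged stable/unstable by the sign of the drift derivative.
    """
    if c < 0 or K <= 0:
        raise ValueError("require c >= 0 and K > 0")
    roots = [0.0]
    poly = np.roots([1.0, -K, 1.0 + c * K, -K])
    real = sorted(
        float(z.real) for z in poly if abs(z.imag) < 1e-9 and z.real > 1e-9
    )
    # Drop (near-)double roots at a fold: keep roots separated by > 1e-7.
    for x0 in real:
        if roots and abs(x0 - roots[-1]) <= 1e-7:
            continue
        lo, hi = x0 - 1e-4, x0 + 1e-4
        f_lo, f_hi = ass_drift(lo, c, K), ass_drift(hi, c, K)
        if f_lo * f_hi < 0:
            x0 = brentq(lambda x: float(ass_drift(x, c, K)), lo, hi, xtol=1e-12)
        roots.append(x0)
    out = []
    for x0 in roots:
        slope = _ass_drift_derivative(x0, c, K)
        out.append((x0, "stable" if slope < 0 else "unstable"))
    return out


def _count_positive_equilibria(c: float, K: float) -> int:
    return sum(1 for x, _ in skeleton_equilibria(c, K) if x > 1e-9)


@lru_cache(maxsize=32)
def find_fold_points(K: float = 11.0) -> tuple[float, float]:
    """Locate the two saddle-node folds bracketing the bistable window.

    The equilibrium count of the skeleton jumps 1 -> 3 -> 1 as c crosses the
    folds; each transition is located by bisection to 1e-6 in c.
    """
    c_grid = np.arange(0.01, 10.0, 0.01)
    counts = np.array([_count_positive_equilibria(c, K) for c in c_grid])
    jumps = np.flatnonzero(np.diff(counts) != 0)
    if len(jumps) < 2 or counts.max() < 3:
        raise BistabilityError(f"no bistable window found for K={K}")

    def bisect(lo: float, hi: float, want_three_low: bool) -> float:
        # want_three_low: True if the three-equilibria side is at lo.
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            three = _count_positive_equilibria(mid, K) == 3
            if three == want_three_low:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-7:
                break
        return 0.5 * (lo + hi)

    c_lower = bisect(c_grid[jumps[0]], c_grid[jumps[0] + 1], want_three_low=False)
    c_upper = bisect(c_grid[jumps[-1]], c_grid[jumps[-1] + 1], want_three_low=True)
    return (c_lower, c_upper)


def _branch_equilibrium(c: float, K: float, branch: str) -> float:
    stable = [x for x, s in skeleton_equilibria(c, K) if s == "stable" and x > 1e-9]
    if len(stable) >= 2:
        return min(stable) if branch == "lower" else max(stable)
    c_lower, c_upper = find_fold_points(K)
    have = "upper" if c < c_lower else "lower"
    if branch == have and stable:
        return stable[0]
    raise BistabilityError(
        f"the {branch} branch has no equilibrium at c={c} "
        f"(bistable window is [{c_lower:.4f}, {c_upper:.4f}] for K={K})"
    )


def simulate_ass(
    params: ASSParams,
    n_samples: int,
    record_step: float = 1.0,
) -> RegimeSeries:
    """Euler-Maruyama path of the stochastic grazing model.

    The path starts on the skeleton equilibrium of the requested branch and
    records one sample per ``record_step`` time units (the first sample is
    the initial state).  The state is floored at 1e-12: Gaussian increments
    can formally cross zero, though at sigma = 0.01 they never do in
    practice.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    steps_per_record = int(round(record_step / params.dt))
    if steps_per_record < 1:
        raise ValueError("record_step must be >= dt")
    x = _branch_equilibrium(params.c, params.K, params.branch)
    rng = np.random.default_rng(params.seed)
    c, K, dt, sigma = params.c, params.K, params.dt, params.sigma
    noise_scale = sigma * np.sqrt(dt)
    values = np.empty(n_samples)
    values[0] = x
    for i in range(1, n_samples):
        eps = rng.standard_normal(steps_per_record)
        for k in range(steps_per_record):
            x = x + (x * (1 - x / K) - c * x * x / (1 + x * x)) * dt
            x += noise_scale * eps[k]
            if x < 1e-12:
                x = 1e-12
        values[i] = x
    if not np.all(np.isfinite(values)):
        raise SimulationError("non-finite state in stochastic path")
    times = np.arange(n_samples) * record_step
    label = "SS1" if params.branch == "lower" else "SS2"
    return RegimeSeries(values, times, regime_label=label, variable_name="x")
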
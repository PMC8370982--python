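"""Replicated detection-probability landscapes.

The test's power is mapped on two parameter grids: (series length x
observation noise) for pairs of food-chain regimes, and (series length x
harvest rate) for the two basins of the stochastic grazing model.  Each grid
cell runs the directional test on independently drawn replicate series and
reports the fraction of replicates that detected a dynamical difference at
the stated alpha.

Replicates differ in their stochastic elements only: for the deterministic
food chain those are the observation-noise draw and the window phase along
one long post-burn-in trajectory; for the stochastic model each replicate is
a fresh path.  All child random streams descend deterministically from one
base seed and the cell coordinates, so a landscape is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import BistabilityError
from .regime_test import directional_regime_test
from .series import RegimeSeries
from .simulators import (
    ASSParams,
    FoodChainParams,
    add_observation_noise,
    classify_food_chain_regime,
    find_fold_points,
    sample_series,
    simulate_ass,
    simulate_food_chain,
)

__all__ = [
    "LandscapeGrid",
    "LandscapeResult",
    "FoodChainEnsemble",
    "FOOD_CHAIN_REGIMES",
    "food_chain_grid",
    "ass_grid",
    "detection_probability_cell",
    "food_chain_landscape",
    "ass_landscape",
]

#: The four study regimes of the food chain, by carrying capacity.
FOOD_CHAIN_REGIMES: dict[str, float] = {
    "A": 0.78,   # equilibrium
    "B": 0.85,   # two-point limit cycle
    "C": 0.92,   # four-point limit cycle
    "D": 0.997,  # chaos
}


@dataclass(frozen=True)
class LandscapeGrid:
    """A (length x second-axis) grid of test conditions."""

    lengths: tuple[int, ...]
    second_axis: tuple[float, ...]
    n_replicates: int = 100
    alpha: float = 0.05
    mode: str = "multivariate"
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", tuple(int(v) for v in self.lengths))
        object.__setattr__(
            self, "second_axis", tuple(float(v) for v in self.second_axis)
        )
        for axis in (self.lengths, self.second_axis):
            if len(axis) == 0:
                raise ValueError("grid axes must be non-empty")
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise ValueError("grid axes must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.lengths) * len(self.second_axis)

    def cell_seed(self, i_length: int, i_axis: int) -> int:
        """Deterministic child seed for one cell of the grid."""
        ss = np.random.SeedSequence([self.base_seed, i_length, i_axis])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def food_chain_grid(n_replicates: int = 100, base_seed: int = 0) -> LandscapeGrid:
    """The published food-chain protocol grid: lengths 10..100 by 10 and
    observation noise 0.01..0.30 by 0.01 (300 cells)."""
    return LandscapeGrid(
        lengths=tuple(range(10, 101, 10)),
        second_axis=tuple(np.round(np.arange(0.01, 0.301, 0.01), 2)),
        n_replicates=n_replicates,
        mode="multivariate",
        base_seed=base_seed,
    )


def ass_grid(n_replicates: int = 100, base_seed: int = 0) -> LandscapeGrid:
    """The published stochastic-model grid: lengths 50..150 by 10 and
    harvest rate 1.83..2.73 by 0.05 (209 cells)."""
    return LandscapeGrid(
        lengths=tuple(range(50, 151, 10)),
        second_axis=tuple(np.round(np.arange(1.83, 2.731, 0.05), 2)),
        n_replicates=n_replicates,
        mode="univariate",
        base_seed=base_seed,
    )


@dataclass
class LandscapeResult:
    """Detection probabilities over a grid, with replicate bookkeeping."""

    grid: LandscapeGrid
    probability: np.ndarray       # shape (len(lengths), len(second_axis))
    detections: np.ndarray        # integer counts, same shape
    replicates: np.ndarray        # replicates actually run per cell
    direction: str = ""           # e.g. "B|A": target regime | library regime
    axis_name: str = "noise"

    def __post_init__(self) -> None:
        shape = (len(self.grid.lengths), len(self.grid.second_axis))
        for arr in (self.probability, self.detections, self.replicates):
            if arr.shape != shape:
                raise ValueError(f"matrix shape must be {shape}")
        finite = self.probability[np.isfinite(self.probability)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def standard_error(self) -> np.ndarray:
        """Binomial standard error sqrt(p(1-p)/n) per cell."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(
                self.probability * (1 - self.probability) / self.replicates
            )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per cell."""
        rows = []
        se = self.standard_error
        for i, length in enumerate(self.grid.lengths):
            for j, v in enumerate(self.grid.second_axis):
                rows.append(
                    dict(
                        length=length,
                        **{self.axis_name: v},
                        direction=self.direction,
                        detections=int(self.detections[i, j]),
                        replicates=int(self.replicates[i, j]),
                        probability=self.probability[i, j],
                        se=se[i, j],
                    )
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# food-chain replicate factory


class FoodChainEnsemble:
    """Replicate factory over cached deterministic food-chain trajectories.

    One long post-burn-in trajectory per regime is integrated once, sampled
    (every fifth unit-step point), and reused: each replicate takes a
    random-phase window of the requested length and adds a fresh
    observation-noise draw scaled to the species' deterministic sd.

    For the equilibrium regime the deterministic sampled trajectory is
    numerically constant, so its own sd cannot scale the noise; the noise
    scale is then floored at the magnitude of the equilibrium itself.  After
    the mandatory standardization that regime is white noise around the
    fixed point whatever rho is — the intended "stochastic equilibrium".
    """

    def __init__(
        self,
        burn_in: float = 10000.0,
        pool_duration: float = 1500.0,
        every: int = 5,
    ):
        self.burn_in = burn_in
        self.pool_duration = pool_duration
        self.every = every
        self._pools: dict[str, dict[str, np.ndarray]] = {}
        self._scales: dict[str, dict[str, float]] = {}

    def _ensure(self, code: str) -> None:
        if code in self._pools:
            return
        if code not in FOOD_CHAIN_REGIMES:
            raise ValueError(
                f"unknown regime code {code!r}; choose from "
                f"{sorted(FOOD_CHAIN_REGIMES)}"
            )
        params = FoodChainParams(K=FOOD_CHAIN_REGIMES[code])
        traj = simulate_food_chain(
            params,
            total_time=self.burn_in + self.pool_duration,
            burn_in=self.burn_in,
        )
        pools, scales = {}, {}
        for var, series in traj.items():
            sampled = sample_series(series, every=self.every)
            pools[var] = sampled.values
            sd = float(np.std(sampled.values, ddof=1))
            mean = abs(float(np.mean(sampled.values)))
            if sd < 1e-6 * max(1.0, mean):
                sd = max(mean, 1.0)
                pools[var] = np.full_like(pools[var], np.mean(sampled.values))
            scales[var] = sd
        self._pools[code] = pools
        self._scales[code] = scales

    @property
    def pool_length(self) -> int:
        return int(self.pool_duration // self.every)

    def deterministic_pool(self, code: str) -> dict[str, np.ndarray]:
        self._ensure(code)
        return self._pools[code]

    def noise_scale(self, code: str) -> dict[str, float]:
        self._ensure(code)
        return self._scales[code]

    def draw(
        self,
        code: str,
        length: int,
        rho: float,
        rng: np.random.Generator,
    ) -> dict[str, RegimeSeries]:
        """One replicate: random-phase window plus fresh observation noise."""
        self._ensure(code)
        pools, scales = self._pools[code], self._scales[code]
        pool_len = len(next(iter(pools.values())))
        if length > pool_len:
            raise ValueError(
                f"requested length {length} exceeds the cached pool "
                f"({pool_len} samples)"
            )
        start = int(rng.integers(0, pool_len - length + 1))
        times = np.arange(length, dtype=float) * self.every
        out = {}
        for var, pool in pools.items():
            window = pool[start : start + length]
            noisy = window + rho * scales[var] * rng.standard_normal(length)
            out[var] = RegimeSeries(
                noisy, times, regime_label=code, variable_name=var
            )
        return out

    def factory(self, code: str) -> Callable:
        """A ``(length, rho, rng) -> bundle`` replicate factory for one regime."""
        self._ensure(code)
        return lambda length, rho, rng: self.draw(code, length, rho, rng)


# ---------------------------------------------------------------------------
# cells and landscapes


def detection_probability_cell(
    regime_i_factory: Callable,
    regime_j_factory: Callable,
    length: int,
    axis_value: float,
    n_replicates: int,
    alpha: float,
    seed: int,
    mode: str = "multivariate",
    config: RunConfig | None = None,
    **config_overrides,
) -> tuple[float, int]:
    """Fraction of replicate tests that detect a dynamical difference.

    Each replicate draws a fresh target bundle from regime i (which also
    serves as its own within-library) and an independent across-library
    bundle from regime j, then runs the directional test at ``alpha``.
    Returns ``(probability, detections)``.
    """
    base = config if config is not None else RunConfig(mode=mode)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    detections = 0
    for child in children:
        rng = np.random.default_rng(child)
        target = regime_i_factory(length, axis_value, rng)
        across = regime_j_factory(length, axis_value, rng)
        perm_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        try:
            result = directional_regime_test(
                target, target, across, mode=mode, config=base,
                alpha=alpha, seed=perm_seed, **config_overrides,
            )
        except Exception as exc:
            raise type(exc)(
                f"{exc} [cell length={length}, axis={axis_value}]"
            ) from exc
        detections += int(result.significant)
    return detections / n_replicates, detections


def food_chain_landscape(
    regime_i: str,
    regime_j: str,
    grid: LandscapeGrid,
    ensemble: FoodChainEnsemble | None = None,
    predictor: str = "P",
    responses: tuple[str, ...] = ("C", "R"),
) -> LandscapeResult:
    """Detection-probability landscape for one ordered food-chain regime pair.

    Regime i is the predicted (target) regime, regime j the across-regime
    library; the multivariate cross-map uses the predator to predict the
    consumer and the resource by default.  The second grid axis is the
    observation-noise level rho.
    """
    if ensemble is None:
        ensemble = FoodChainEnsemble()
    fac_i = ensemble.factory(regime_i)
    fac_j = ensemble.factory(regime_j)
    shape = (len(grid.lengths), len(grid.second_axis))
    prob = np.empty(shape)
    det = np.zeros(shape, dtype=int)
    reps = np.full(shape, grid.n_replicates, dtype=int)
    for i, length in enumerate(grid.lengths):
        for j, rho in enumerate(grid.second_axis):
            p, d = detection_probability_cell(
                fac_i, fac_j, length, rho,
                n_replicates=grid.n_replicates, alpha=grid.alpha,
                seed=grid.cell_seed(i, j), mode="multivariate",
                predictor=predictor, responses=responses,
            )
            prob[i, j], det[i, j] = p, d
    return LandscapeResult(
        grid=grid, probability=prob, detections=det, replicates=reps,
        direction=f"{regime_i}|{regime_j}", axis_name="noise",
    )


def ass_landscape(
    grid: LandscapeGrid,
    K: float = 11.0,
    sigma: float = 0.01,
    dt: float = 0.01,
) -> tuple[LandscapeResult, LandscapeResult]:
    """Landscapes for both directions of the stochastic bistable model.

    For each cell one path per basin is simulated (SS1 on the lower branch,
    SS2 on the upper), each standardized, and both directional univariate
    tests are run.  Returns ``(target_ss1, target_ss2)``: the first result
    predicts SS1 from SS2's library, the second the reverse.  Cells whose
    harvest rate falls outside the bistable window are marked invalid (NaN)
    rather than silently skipped.
    """
    c_lower, c_upper = find_fold_points(K)
    shape = (len(grid.lengths), len(grid.second_axis))
    prob = [np.full(shape, np.nan) for _ in range(2)]
    det = [np.zeros(shape, dtype=int) for _ in range(2)]
    reps = [np.zeros(shape, dtype=int) for _ in range(2)]
    for i, length in enumerate(grid.lengths):
        for j, c in enumerate(grid.second_axis):
            if not (c_lower < c < c_upper):
                continue  # invalid cell, stays NaN
            children = np.random.SeedSequence(grid.cell_seed(i, j)).spawn(
                grid.n_replicates
            )
            hits = [0, 0]
            for child in children:
                s1, s2 = child.spawn(2)
                seed1 = int(s1.generate_state(1)[0] & 0x7FFFFFFF)
                seed2 = int(s2.generate_state(1)[0] & 0x7FFFFFFF)
                ss1 = simulate_ass(
                    ASSParams(c=c, K=K, sigma=sigma, dt=dt,
                              branch="lower", seed=seed1),
                    n_samples=length,
                )
                ss2 = simulate_ass(
                    ASSParams(c=c, K=K, sigma=sigma, dt=dt,
                              branch="upper", seed=seed2),
                    n_samples=length,
                )
                perm_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
                r1 = directional_regime_test(
                    ss1, ss1, ss2, mode="univariate",
                    alpha=grid.alpha, seed=perm_seed,
                )
                r2 = directional_regime_test(
                    ss2, ss2, ss1, mode="univariate",
                    alpha=grid.alpha, seed=perm_seed + 1,
                )
                hits[0] += int(r1.significant)
                hits[1] += int(r2.significant)
            for k in range(2):
                prob[k][i, j] = hits[k] / grid.n_replicates
                det[k][i, j] = hits[k]
                reps[k][i, j] = grid.n_replicates
    res = tuple(
        LandscapeResult(
            grid=grid, probability=prob[k], detections=det[k],
            replicates=reps[k], direction=d, axis_name="harvest_rate",
        )
        for k, d in enumerate(("SS1|SS2", "SS2|SS1"))
    )
    return res
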
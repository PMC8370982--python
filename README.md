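# attractortest

Do two segments of an ecological time series represent *qualitatively
different dynamical attractors* — say, an equilibrium before a regime
shift and a cycle after it?  `attractortest` answers that with a formal
test built on empirical dynamic modeling, for ecologists and
time-series analysts working with population or community data split
into two labeled regimes.

## The test

Each regime's attractor is reconstructed by delay embedding
(`y(t) = <Y(t), Y(t-1), ..., Y(t-(E-1))>`, with `E` chosen by
leave-one-out forecast skill).  The target regime *i* is then forecast
twice by simplex projection — from its own library `M_i`
(within-regime) and from the contrasting regime's library `M_j`
(across-regime) — and the mean absolute prediction errors are compared:

    D = MAPE_A − MAPE_W,      MAPE = (1/n) Σ |Yhat(t) − Y(t)|

If the regimes share an attractor, either library predicts regime *i*
about equally well and `D ≈ 0`; if they do not, across-regime forecasts
degrade and `D > 0`.  Significance comes from a one-sided permutation
test (pool all errors, re-deal into two groups of the original sizes,
1000 permutations, alpha = 0.05).  Both a univariate mode (one-step-ahead
self-prediction) and a multivariate cross-map mode (the embedding of one
variable predicts another at the same times) are provided.

The package also ships the two simulators used to characterize the test —
a tri-trophic food chain whose carrying capacity K selects equilibrium
(K=0.78), two-point cycle (0.85), four-point cycle (0.92) or chaos
(0.997), and a stochastic bistable grazing model
`dx = [x(1−x/K) − cx²/(1+x²)]dt + σdW` — plus replicated
detection-probability landscapes over series length × observation noise
and series length × harvest rate.  See `docs/methods.md` for the full
model account.

## Worked example

Draw a two-point-cycle regime and a four-point-cycle regime from the food
chain (length 100, 5% observation noise) and ask whether the four-point
library can predict the two-point data:

```python
import numpy as np
from attractortest import FoodChainEnsemble
from attractortest.regime_test import directional_regime_test

ensemble = FoodChainEnsemble()
rng = np.random.default_rng(0)
two_point = ensemble.draw("B", 100, 0.05, rng)
four_point = ensemble.draw("C", 100, 0.05, rng)

result = directional_regime_test(
    two_point, two_point, four_point,
    mode="multivariate", predictor="P", responses=("C", "R"), seed=1,
)
print(f"MAPE_W = {result.mape_within:.3f}  (n = {result.n_within})")
print(f"MAPE_A = {result.mape_across:.3f}  (n = {result.n_across})")
print(f"E_within = {result.E_within}, E_across = {result.E_across}")
print(f"p = {result.p_value:.4f}  ->  significant: {result.significant}")
```

prints

```
MAPE_W = 0.046  (n = 182)
MAPE_A = 0.275  (n = 194)
E_within = 10, E_across = 4
p = 0.0010  ->  significant: True
```

Within-regime forecasts of the two-point cycle are accurate on the
standardized scale (MAPE 0.05), forecasts informed by the four-point
regime are six times worse (0.28), and no permutation of the pooled
errors reproduces that gap — the two regimes are alternative attractors.
The forecasters are also available as scikit-learn style estimators
(`SimplexForecaster`, `CrossMapForecaster`) with `fit`/`predict` and
`get_params`/`set_params`.

A command-line surface wraps the same operations:

```
attractortest simulate-foodchain --k 0.85 --rho 0.05 --seed 1 --out b.csv
attractortest simulate-ass --c 2.2 --branch lower --n 100 --seed 7 --out ss1.csv
attractortest test --input series.csv --breakpoint 120 --mode univariate --seed 0
attractortest landscape-ass --reduced --seed 0 --out grid.csv
```

`test` accepts a single file with a breakpoint or a `regime` column, or
two files; it runs both directions and emits JSON records.  Exit status
reflects errors only, never non-significance.

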
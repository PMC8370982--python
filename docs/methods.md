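# Methods

## The question and the test

Two segments of an ecological time series are suspected to be governed by
different dynamical attractors — say an equilibrium before a critical
transition and a cycle after it.  `attractortest` turns that suspicion into
a one-sided statistical test built on empirical dynamic modeling (EDM).

By Takens' theorem, the attractor of a deterministic system can be
reconstructed from lagged copies of a single observed variable.  If two
regimes share an attractor, a reconstruction from either regime should
forecast the other regime about as well as it forecasts itself.  The test
therefore forecasts a target regime *i* twice — from its own library
(within-regime, `Yhat_i | M_i`) and from the contrasting regime's library
(across-regime, `Yhat_i | M_j`) — and compares mean absolute prediction
errors:

    D = MAPE_A − MAPE_W ,

rejecting the hypothesis of a shared attractor when D is larger than
expected under exchangeable errors.  Absolute rather than squared errors
damp the heavy right tail that simplex forecasts of cyclic data produce.

## Forecasting machinery

* **Delay embedding.**  Lag fixed at one sample; vectors
  `<Y(t), Y(t-1), ..., Y(t-(E-1))>`; a length-n series yields `n - E + 1`
  library vectors.
* **Simplex projection.**  A forecast is the weighted average of the
  successor (univariate, one step ahead) or contemporaneous response
  (multivariate cross-map) values of the `E+1` nearest library vectors,
  with weights `w_m ∝ exp(-d_m / d_1)`.  If the nearest distance is exactly
  zero the formula's continuity limit applies: equal weights over all
  zero-distance neighbors.  Distance ties at the `(E+1)`-th neighbor break
  to the smaller anchor time, which makes runs bit-reproducible and lets
  the test suite compare against an exhaustive pure-Python reference
  implementation exactly.
* **Embedding dimension.**  The single estimated parameter.  For each
  `E` in `1..E_max` (default `min(10, n//2 - 1)`), the series forecasts
  itself one step ahead with the self vector excluded, and the `E`
  maximizing the Pearson correlation between observations and forecasts
  wins; ties go to the smallest `E`.
* **Self-exclusion.**  Within-regime forecasts always exclude the library
  vector anchored at the predicted time — otherwise the zero-distance
  self-match makes within-regime errors identically zero and the test
  vacuous.  No wider Theiler window is applied by default (`theiler`
  is configurable); temporally adjacent vectors remain eligible neighbors.
* **Across-regime embedding.**  Both the library and the target's query
  vectors use the *library* regime's `E`, since a neighbor search requires
  equal dimensions and `E` characterizes the library attractor.
* **Multivariate mode.**  The embedding of a predictor variable X maps
  onto responses at the same times (no +1 shift).  `E` is selected on the
  predictor's own univariate skill.  Error sets from several responses
  (by default: predator predicts consumer and resource) are pooled.

## The permutation test

All within and across absolute errors are pooled and re-dealt at random
into two groups of the original sizes; `D` is recomputed for each
re-dealing and the one-sided p-value is the add-one-smoothed fraction of
permuted `D` at least as large as the observed one (1000 permutations,
alpha 0.05 by default; significance at alpha 0.05 is equivalent to the
95th-percentile rule).  When the number of distinct assignments does not
exceed the permutation budget the test enumerates them all, so small
problems get exact p-values.  Group sizes generally differ because the two
libraries select different `E`.

The label-shuffle null assumes exchangeable errors.  Forecast errors along
a trajectory are serially correlated, so the test is *approximate*: on
same-attractor (null) data it can reject above or below the nominal level
depending on regime and noise (measured 0.00–0.16 at alpha 0.05 across
diagonal food-chain cells).  The within-library `E` is also selected on
the very series being predicted, a mild in-sample optimism.  Both effects
are inherent to the published procedure; see "Known limitations".

## Synthetic regimes

### Tri-trophic food chain

    dR/dt = R(1 - R/K) - x_c y_c C R/(R + R0)
    dC/dt = x_c C(-1 + y_c R/(R + R0)) - x_p y_p P C/(C + C0)
    dP/dt = x_p P(-1 + y_p C/(C + C0))

with bioenergetic constants `x_c=0.4, y_c=2.009, x_p=0.08, y_p=2.876,
R0=0.16129, C0=0.5`.  Carrying capacity selects the attractor:
K=0.78 equilibrium, K=0.85 simple ("two-point") limit cycle of period
≈ 52 time units, K=0.92 period-doubled ("four-point") cycle,
K=0.997 chaos.  Numerical choices:

* adaptive Runge–Kutta (RK45) at rtol 1e-8 / atol 1e-10;
* initial state (0.8, 0.2, 1.0).  The model is bistable between the
  coexistence attractor and a predator-free resource–consumer cycle;
  symmetric starts such as (0.5, 0.5, 0.5) lose the predator for
  K ≥ 0.85, so the default start is chosen inside the coexistence basin
  for all four K;
* burn-in 10000 time units, set by the K=0.92 cycle whose transient
  outlasts several thousand time units; output every 1 time unit;
* "every fifth point" subsampling, i.e. a 5-time-unit sampling interval,
  which gives ≈ 10.4 samples per cycle of the K=0.85 attractor;
* observation noise `N(t) = N'(t) + rho·e(t)`, `e ~ Normal(0, sd(N'))`
  with the species' own deterministic sampled sd (n−1 denominator), added
  after subsampling.

The regime classifier standardizes a trajectory, refines local extrema by
parabolic interpolation, clusters extremum levels (relative tolerance
1e-3 of the standardized range), and counts maximum plus minimum levels —
the "n-point" convention, in which a simple cycle is 2-point and its first
period-doubling 4-point.  Extrema that neither settle into at most 8
levels nor repeat in a fixed rotation mark the trajectory aperiodic.

### Stochastic alternative stable states

    dx = [ x(1 - x/K) - c x² / (1 + x²) ] dt + sigma dW

the canonical grazing model, with K=11, sigma=0.01, Euler–Maruyama step
dt=0.01, one sample per time unit, and the state floored at 1e-12.  Paths
start on the noise-free skeleton equilibrium of the chosen branch; sigma
is small enough that paths never flicker between basins.  The skeleton's
positive equilibria are the roots of a cubic (found from the companion
polynomial and polished by bisection to 1e-9, stability from the drift
derivative); the two saddle-node folds are located by bisection on the
equilibrium count to 1e-6 in c, giving c_lower = 1.808 and
c_upper = 2.844 at K=11, so the study's harvest-rate grid 1.83..2.73 lies
strictly inside the bistable window with its ends close to the folds.

A note on the drift: the grazing term is sometimes printed with a
`1 − x²` denominator, which is singular at x=1 and yields no bistable
window bracketing the study's harvest rates; this package uses the
canonical `1 + x²` form, which does.

## Detection-probability landscapes

Each grid cell runs the directional test on independently drawn replicate
pairs and reports the detected fraction with its binomial standard error.
For the food chain, one long deterministic trajectory per regime is
integrated once; replicates differ in window phase (uniform over the
cached pool) and in the observation-noise draw.  For the stochastic model
every replicate simulates a fresh path per basin.  All child random
streams descend deterministically from one base seed and the cell
coordinates, so landscapes are bit-reproducible.

The published grids are 10..100 × 0.01..0.30 (300 cells, multivariate,
100 replicates) and 50..150 × 1.83..2.73 (209 cells, univariate).  The
test suite and the reproduction script run reduced versions (single rows,
20–50 replicates; 500 replicates only for the null-rate check), sizes
chosen so the whole suite completes in a few minutes.

### The "stochastic equilibrium" regime

At K=0.78 the post-burn-in trajectory is constant to ~1e-7, so the
observation-noise scale `rho·sd(N')` degenerates to zero and the regime
would be untestable (zero variance).  The ensemble therefore floors the
noise scale at the species' equilibrium magnitude; because every series is
standardized before testing, this regime reduces to white noise around the
fixed point *regardless of rho* — a pure stochastic equilibrium.  The
generator consequently cannot emulate any residual deterministic transient
a finite burn-in might leave in real re-analyses of this model.

## What the synthetic tests do and do not show

The generators produce regimes with clean separations (deterministic
skeletons, stationary noise, known breakpoints).  Passing tests show the
machinery reproduces the published protocol's structure and its
qualitative power pattern: cyclic targets are detected against contrasting
libraries essentially always at low noise; stochastic regimes are
distinguishable only near a fold, and then only with long series.  They do
not show calibration on real data, where irregular sampling, trends,
non-stationary noise and unknown breakpoints all intrude.

## Known limitations

* The permutation null ignores the serial correlation of forecast errors;
  on same-attractor data the realized rejection rate at alpha 0.05 ranged
  from 0.00 to 0.16 across diagonal cells.  Treat p-values near the
  threshold with caution, and prefer long series where the error count,
  not the error correlation, dominates.
* A completely unpredictable target can still yield MAPE_A > MAPE_W:
  within-regime simplex forecasts of white noise are shrunken averages,
  while across-regime forecasts from a low-dimensional cyclic library
  retain near-unit dispersion.  Detection of "dynamical difference" for a
  noise-dominated target against a simple cycle library therefore runs
  well above alpha (up to ~0.9 against the 2-point-cycle library in the
  study conditions).  A significant result means the across library fails
  to reproduce the target's error distribution — not necessarily that the
  target itself is internally driven.
* Lag is fixed at one sample; horizons beyond one step, S-map local
  linear forecasting, and convergent cross-mapping convergence tests are
  out of scope.
* Missing-value imputation assumes a local-level (random walk plus noise)
  structure, the minimal choice for a generic Kalman smoother; series are
  imputed before any regime split.
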
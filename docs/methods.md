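# Methods

This note records the model definition, all fixed parameters, the
synthetic target generator, and the numerical design decisions of the
`eicpg` package.

## 1. Network model

Rate network of `N_tot = N_E + N_I` neurons with Euler-forward dynamics

    x(t+dt) = x(t) + (dt/tau) * ( -x(t) + J_rec phi(x(t)) + J_fb y(t) + J_in U(t) )
    y(t)    = W phi(x(t))

| quantity | value | notes |
|---|---|---|
| `tau` | 0.01 s | neuronal time constant |
| `dt` | 0.005 s | integration step (`dt/tau = 0.5`) |
| `phi` | `max(0, tanh x)` | rectified tanh; sigmoid available via `transfer="sigmoid"` |
| `U(t)` | `1 + sin(omega t)` | `omega = 2 pi / stride_period`, phase reset each stride |
| `J_in` | i.i.d. `N(0, 1/3)` | input weights, `v_in = 1/3` |
| `J_fb` | i.i.d. `U[-1, 1]` | feedback of the readout |
| `x(0)` | i.i.d. `N(0, 1)` | redrawn at each training iteration |
| `W` | `0` initially | only trained weights |

**Dale's law (column convention).** Column `j` of `J_rec` holds neuron
`j`'s outgoing weights. The first `N_E` columns are nonnegative, the rest
nonpositive. An entry is nonzero with probability `p` (per population);
nonzero magnitudes are `|N(0, V0)|` with

    V0 = v / (p (1 - 2p/pi)),    v = g^2 / N  (per population).

This choice makes the variance of the full weight set (zeros included)
equal to `v` independently of `p`, and gives the full-set mean
`m = sqrt(2/pi) sqrt(p v / (1 - 2p/pi))`. Self-connections are allowed
(they are a `1/N` effect and the reference derivations do not exclude
them).

**Anatomical imbalance.**

    A = m_E N_E + m_I N_I
      = sqrt(2/pi) ( g_E sqrt(p_E N_E / (1-2p_E/pi)) - g_I sqrt(p_I N_I / (1-2p_I/pi)) )

Note the population size appears in the **numerator** under the square
root. With `N_E = N_I = 375`, `p = 0.1`, `g_tot = sqrt(2*1.5^2)` this
gives the reference operating points `A = -5 -> (g_E, g_I) = (0.92, 1.91)`
and `A = +10 -> (2.12, 0.14)`.

`solve_params_for_imbalance` realizes a target `A` in three modes:

- `by_g`: closed-form quadratic for `(g_E, g_I)` at fixed `g_tot`;
- `by_N`: integer split of `N_tot` at common `(p, g)`; the split is
  rounded, so the achieved `A` carries a one-neuron rounding residual;
  imbalances beyond the one-population extreme (`(A/k)^2 > N_tot`) raise
  an infeasibility error;
- `by_p`: Brent root for `(p_E, p_I)` at fixed density `p_tot`.

## 2. Mean-field theory

Self-consistent description of the input statistics
`x_i ~ N(mu, Delta)` under a quasi-stationary slow drive:

    mu    = A [phi]
    Delta = g_tot^2 [phi^2] + v_in U^2
    [phi^k] = E_z[ phi(mu + sqrt(Delta) z)^k ],  z ~ N(0,1)

solved by damped fixed-point iteration (damping 0.5, tolerance 1e-12)
with a `scipy` root solve as fallback; residuals below 1e-10 are
enforced.

**Quadrature.** The rectified-tanh integrands have a kink at
`z = -mu/sqrt(Delta)`, which defeats Gauss–Hermite rules. Moments are
computed with 96-node Gauss–Legendre on the truncated support
`[max(-mu/sqrt(Delta), -8.5), 8.5]`, where the integrand is smooth;
smooth transfers (sigmoid) use 201-node Gauss–Hermite. Accuracy is
checked against adaptive quadrature (1e-10) and 10^7-sample Monte Carlo.

**Stability.** Linearizing the single-site fluctuation dynamics gives the
variance-gain criterion

    g_tot^2 E[ phi'(mu0 + sqrt(Delta0) z)^2 ] < 1.

The slow drive `U(t) = 1 + sin` passes through zero, and judging
stability at each instantaneous drive value would flag every network
unstable near `U ~ 0` long before anything diverges in simulation.
Because `tau << stride period` but the fluctuation growth integrates over
the cycle, the criterion is evaluated at the **cycle-RMS drive**
`U_eff = sqrt(<U^2>) = sqrt(1.5)`. With this policy the largest stable
value on the grid `{0.5, 0.75, ..., 2.5}` is `g_tot = 2.25` for every
integer `A` in `[-15, 15]`, matching the simulated behaviour; at 2.5 the
gain exceeds 1 for `A` in `[-4, 0]`. A simulation fallback
(`lyapunov_proxy`, twin-trajectory divergence slope) is provided for
regimes where the quasi-stationary assumption is in doubt.

`mft_curves` additionally reports cycle-averaged rate moments and the
E/I current split `(a g_E [phi], -b g_I [phi])`, averaged over a 32-point
midpoint grid of the drive cycle.

## 3. Target signals

Sample rate 200 Hz (= 1/dt, one shared time base).

**Motor primitives** (`primitive_patterns`): five circular Gaussian bumps
(centres 10/30/50/70/90 % of the cycle, width sigma = 8 % cycle,
amplitude 0.8) at a stride frequency `0.6 + 0.25 * speed` Hz for speeds
0.3–2.0 m/s. These are artifact choices emulating bell-shaped locomotor
primitives; they are constants in `eicpg.targets` and can be swapped.

**Synthetic muscle targets** (`synthetic_muscle_targets`): 17 channels
per activity, built as nonnegative random mixtures of 4–5 of the five
primitives (shared mixing matrix across activities), then modulated per
activity by an amplitude scale (0.75 / 0.90 / 1.0) and a global centre
shift (0 / +4 % / -5 % of the cycle), peak-normalized to `U(0.45, 0.95)`
and low-pass filtered (2nd-order Butterworth, 20 Hz, forward–backward =
zero phase). Activity stride periods: slow walk 1.30 s, fast walk 1.00 s,
run 0.72 s. The shared mixing keeps the target set's effective
dimensionality at or below 8 (5 primitives + per-activity modulations),
emulating the low-dimensional synergy structure of measured EMG. What the
generator does **not** emulate: EMG noise, step-to-step variability,
bilateral asymmetries, or muscle-specific phase relationships beyond the
primitive mixture.

**Assembly** (`assemble_signal`): train mode = 3 activities x 5
consecutive strides (order slow, fast, run — the protocol order is a
package choice); test mode = 21 strides, 7 per activity, seed-shuffled.
Strides are concatenated with a single interpolated sample (neighbour
midpoint) at each boundary; 50 samples are trimmed at both ends; the
drive phase resets at each stride onset so every stride starts at
`U = 1` rising. The first test stride is excluded from all evaluation
(initialization transient), leaving 20 evaluated strides.

Throughout, `omega` denotes the angular stride frequency
`2 pi / period`; the running stride **period** is fixed at 0.72 s
(`ACTIVITY_PERIODS["run"] = 0.72`).

## 4. Training

FORCE-style recursive least squares on the readout only, with the
network running closed-loop on its own output feedback:

    k = P r / (1 + r' P r);  e = W r - y*;  W <- W - e k';  P <- P - k (P r)'

`P0 = I / alpha` with `alpha = 1.0`, update every 2 steps, 5 training
iterations, `x` redrawn from `N(0,1)` at each iteration start. One RLS
pass is algebraically a ridge regression with penalty `alpha` (verified
against a direct solve). Non-finite updates raise a training-divergence
error carrying the iteration index.

## 5. Outcome metrics

- **Stride success / performance**: per muscle and per evaluated stride,
  success iff RMSE <= 0.05; performance = % successful muscle-stride
  cells (first stride excluded).
- **Effective dimensionality**: smallest number of principal components
  reaching 99 % explained variance (time samples as observations);
  constant data defined as 0.
- **Coactivation index**: traces max-normalized over the evaluation
  window; `CAI(t) = 2 min(Y1, Y2) / (Y1 + Y2)` averaged over active time
  points, then over all unordered muscle pairs; all-zero traces give NaN
  with a warning.
- **Between-task variance**: strides resampled to a 101-point 0–100 %
  cycle grid, averaged within task; population variance (divisor `n`)
  across the task means, averaged over channels and grid points.
- **Firing-rate statistics**: across-neuron mean/variance (time
  averaged) of rates and activations; skewness of the pooled
  (neurons x time) rate distribution (per-neuron option available);
  exactly constant rates give skewness 0.

## 6. Experiments and problem sizes

`run_sweep` crosses an imbalance grid with one varied anatomical quantity
per mode, trains `n_instances` networks per cell, and aggregates. Seeds
derive deterministically from `SeedSequence([master, cell_index,
instance])`; each instance seed expands into independent connectivity /
initialization / sequence streams, so every result table is reproducible
from `(config, seed)` and test sequences are shared across parameter
settings. Per-cell results are cached as CSV for resumption.

Default desk-scale profile (a deliberate scale-down of the full study,
chosen once): `N_E = N_I = 375` (`N_tot = 750`), `p = 0.1`,
`g_tot = sqrt(2 * 1.5^2) ~ 2.12`, 5 instances, imbalance grid
`{-10, -5, 0, 5, 10}`. At this size the absolute success percentages
differ from full-scale runs; the ordering across imbalances is the robust
outcome. The 5-seed means observed at `(A = -5, 0, +10)` are
approximately `(49, 57, 0.3) %`.

`run_mft_comparison` drives untrained networks (zero readout) and
compares time-averaged population mean input and mean rate against the
cycle-averaged theory. `run_generalization` trains on the five primitive
channels at speeds `{0.6, 1.2, 1.6}` m/s and tests on the 0.3–2.0 m/s
grid.

## 7. External targets

`load_external_targets` ingests 17-channel target sets from HDF5 or CSV
(+JSON metadata), validates the `[0, 1]` range (clipping with a warning)
and feeds the same evaluation pipeline. Archival gait recordings are not
bundled (binary data, network download); the ingestion and PCA pipeline
is exercised on locally generated files instead.
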
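# Methods

## The model

`bndd` frames discontinuity-based quasi-experimental inference as Bayesian
model comparison between two Gaussian-process regressions of the response
`y` on the assignment variable `x` with a known threshold `x0`:

* **Continuous model M0** — one GP over all observations,
  `y_i ~ N(f(x_i), sigma_n^2)`, `f ~ GP(mu, k(x, x'; theta))`.
* **Discontinuous model M1** — the latent processes on the two sides of
  the threshold are independent.  The covariance is masked to zero across
  the partition, so the Gram matrix is block-diagonal.  In RD and geo
  mode both blocks share one hyperparameter set; in ITS mode each side
  has its own hyperparameters (an intervention may change length-scale or
  spectral content, not just the level) and the two sides are fitted as
  separate GPs whose log marginal likelihoods add.

The threshold convention is `x >= x0` treated (the boundary point belongs
to the post side).  In geo mode the "threshold" is a boundary polyline
and side assignment is the sign of the cross product against the nearest
segment.

Evidence for each model is approximated by the BIC form

    log p(D | M) ~= log p(y | x, theta_hat, M) - (l / 2) log n,

with `theta_hat` the optimised hyperparameters and `l` their count.
`l` includes the observation-noise variance and any optimised
mean-function parameters; a fixed empirical-mean constant is not
optimised and therefore not counted.  Because the RD discontinuous model
shares one `theta` across its blocks, it has exactly the same `l` as the
continuous model with the same kernel family — its complexity penalty
relative to M0 comes entirely from the independence assumption, not from
parameter counting.

For the ITS discontinuous model the two sides have disjoint parameters
and independent likelihood factors, so the Laplace approximation behind
the BIC factorises; we therefore apply the penalty per side with each
side's own sample size:

    log p(D | M1) ~= [lml_A - (l_A/2) log n_A] + [lml_B - (l_B/2) log n_B].

A single shared penalty `((l_A + l_B)/2) log(n_A + n_B)` would overstate
the evidence each side's data carry about the other side's parameters and
systematically tilts the comparison toward M0 by several nats.

The log Bayes factor is the difference of log evidences; with a model
prior (uniform by default) it gives the posterior model probabilities.
The reported effect size is the spike-and-slab model average: a point
mass at zero with weight `p(M0 | D)` and the M1 Gaussian with weight
`p(M1 | D)`.  Its mean `p(M1|D) * m` is always closer to zero than the
conditional estimate `m` — the shrinkage that protects small-effect
regimes from the overconfidence of conditioning on M1.  When several
candidate kernels are supplied, evidences are combined per model by
log-sum-exp under a (uniform) kernel prior into a total Bayes factor, and
the marginal effect sample first draws a (model, kernel) pair and then
that kernel's effect.  A single shared kernel prior is used for both
models.

## Effect sizes

* **RD** — `d | D, M1 ~ N(m, s^2)` with `m` the post-side minus pre-side
  posterior mean, both blocks evaluated exactly at `x0`.  The GP
  posterior mean is continuous on each side, so the one-sided limits
  equal the values at `x0`; the pre-side block simply predicts at `x0`
  even though that point formally belongs to the post side.  For
  stationary kernels `s^2 = 2 sigma_n^2`; the implementation keeps this
  printed identity and offers the sum of the two one-sided latent
  predictive variances behind a flag (`use_predictive_variance`), which
  is also the automatic fallback for non-stationary kernels such as the
  linear kernel.
* **ITS** — an effect curve `m(x)` = post-side fit minus pre-side
  extrapolation on a grid of 200 points from `x0` to `max(x)`, with
  constant variance `sigma_nA^2 + sigma_nB^2`, summarised by the value of
  largest magnitude (the signed value at the argmax of `|m(x)|`).
* **geo** — the same differencing at arc-length-uniform points along the
  boundary polyline, with pointwise variance the sum of the two one-sided
  latent variances; plotted bands are one standard deviation.

## Kernels

`constant`, `linear` (with learnable offset and bias, so the induced
regression spans intercept + slope), `exp` (Matern 1/2 — Markov, level
discontinuities only), `matern32` (value + first derivative), `rbf`
(exponentiated quadratic — discontinuities of any order, given enough
data), and `sm` (spectral mixture).  Matern orders are fixed per family,
not learned.  All positive hyperparameters live on an unconstrained
softplus scale during optimisation; Gram matrices get a jitter of
1e-6 times the mean prior variance before factorisation, escalated
tenfold a few times if the Cholesky still fails.

The spectral mixture kernel

    k(tau) = sum_q w_q cos(2 pi tau mu_q) exp(-2 pi^2 tau^2 sigma_q^2)

is the inverse Fourier transform of a Gaussian mixture over frequency
(all frequencies in cycles per unit of `x`).  It is initialised from the
data: a Lomb-Scargle periodogram on 5000 frequencies up to the
pseudo-Nyquist limit `1/(2 * median spacing)` — valid for unevenly
sampled series — is reduced to its pronounced peaks by subtracting the
95th power percentile and squaring, and a Q-component Gaussian mixture
fitted to draws from that sharpened spectrum supplies initial component
frequencies, widths and weights (weights rescaled so `k(0)` equals the
sample variance).  The periodogram is computed on uncentred `y`, so a
near-constant signal initialises to a DC-like component.  The floor
subtraction and sharpening are initialisation heuristics only; the
marginal-likelihood optimisation refines all parameters.

The number of components `Q` is selected by maximising the BIC evidence
over `Q = 1..q_max` (default 6).  Selecting on the raw marginal
likelihood instead would always prefer larger `Q`, because nothing in the
marginal likelihood at the optimum penalises the 3 extra parameters per
component; the BIC-based choice keeps the selection consistent with the
evidence used in the model comparison itself.

## Optimisation

Multi-restart L-BFGS with analytic gradients of the log marginal
likelihood (default 10 restarts; the scaled-down study reruns use 2-3,
which reproduce the same optima on these problem sizes).  The first
restart starts from the current kernel parameters — for the spectral
mixture, the periodogram initialisation — and later restarts draw
length-scales log-uniformly over `[0.1, 2] x range(x)`, set the signal
variance to `var(y)` and the noise variance to `0.1 var(y)` (spectral
mixture restarts jitter the initialisation lognormally instead).  A
restart is never allowed to end below its own starting value; reaching
the iteration cap counts as a usable optimum.  Everything is driven by a
single integer seed, so repeated runs are bit-identical.

Mean functions: the empirical mean of `y` (fixed, uncounted) for M0 and
the RD/geo M1; each side's own empirical mean for the ITS M1;
`changepoint_constant` — a sigmoid blend of two optimised constants with
fixed steepness `100 / range(x)` — is available for continuous-model
fits where a level shift is not itself the effect of interest (the
heart-rate style of analysis).  Its two constants are counted in `l`.

## Synthetic data

The generators reproduce the simulation studies the package is tested
against:

* **RD** — `x ~ U(-1, 1)`, `y = f(x) + d [x >= 0] + N(0, sigma^2)` with
  eight latent polynomials (`linear`, `quad`, `cubic`, `lee`, `cate1`,
  `cate2`, `ludwig`, `curvature`), defaults `n = 100`, `sigma = 1`.  All
  eight are continuous in value at the threshold; `lee`, `ludwig` and
  `curvature` have first-derivative breaks there by construction, and
  `quad`/`cubic` second/third-order breaks.  The `curvature` post-branch
  quartic coefficient is read as -0.901 (the source table prints it with
  a decimal comma, following the sign pattern of its neighbours).
* **ITS** — `y = f(x) + N(0, 0.2)` at `n = 200` evenly spaced points on
  `[-1, 1]`, `f(x) = sin(12x) + (2/3)cos(25x)` before the threshold and
  the same with both angular frequencies shifted by `alpha` after it.
  The range `[-1, 1]` (not stated by the study) gives roughly 2 and 4
  cycles per side of the two tones at `n = 200` — enough for spectral
  identification.  The `12`, `25` and `alpha` are angular frequencies
  (radians per unit `x`) as written; everything user-facing is in cycles
  per unit.

What these generators do not emulate: heteroscedastic or non-Gaussian
noise, drifting sampling density near the threshold, confounders, and
fuzzy (probabilistic) treatment assignment.  Green tests therefore say
nothing about those failure modes on real data.

## Baselines

* **Two-stage test** — conditions on M1, then tests `d = 0` with a
  two-sided z-test of `m / s`.  It inherits the overconfidence the model
  average is designed to remove.
* **ARMA extrapolation** — the pre-intervention series is fitted with
  ARIMA(p, d, q) over `p, q in [0, 5]`, `d in {0, 1}` (BIC-selected,
  optimiser capped at 50 iterations per candidate, which does not change
  the selected orders on these series) and forecast over the post region.
  RMSE for both methods is measured against the noiseless pre-threshold
  formula extended past the threshold — the counterfactual that the ITS
  effect curve subtracts.  GP extrapolation error pools 20 posterior
  draws.

## Numerical choices and scaled-down study sizes

* Natural logarithms everywhere (Bayes factors, evidences).
* Spike-and-slab sampling defaults to 50,000 draws; the empirical spike
  mass then matches `p(M0|D)` to about three binomial standard errors.
  Density visualisation should apply a KDE to the slab component only —
  a KDE over the point mass is meaningless.
* The packaged study reruns use 10-20 replicates per condition (against
  the originals' 100/20) and 2-3 optimiser restarts; medians across
  replicates are compared, which is insensitive to this scaling on the
  margins we assert.
* Degenerate inputs: a side with fewer than two observations, an empty
  effect grid, an empty kernel set, non-positive scale parameters and
  mismatched input dimensions all raise `ValueError` with the offending
  quantity named; a Gram matrix that stays non-positive-definite after
  jitter escalation raises a numerical error naming the kernel and noise
  level.

## Known limitations

* The evidence is the BIC approximation at optimised hyperparameters,
  not a hyperparameter-integrated marginal likelihood; Bayes factors
  inherit its large-`n`, regular-model assumptions.
* Detection of derivative-only discontinuities is weak in low-noise
  regimes: as noise shrinks, the discontinuous model's handicap from
  discarding cross-threshold correlation grows faster than its gain from
  fitting a modest slope break, so a kink is flagged reliably only when
  the slope change is large relative to the noise-bandwidth trade-off.
  (On `f = |x|` with a slope jump of 2, the Matern-3/2 comparison turns
  decisively positive only around `sigma <= 0.05` at `n = 100`.)
* The spectral-mixture likelihood surface is multimodal; results depend
  on the periodogram initialisation, which assumes the interesting
  structure shows up as periodogram peaks.
* Geo mode fits isotropic kernels on raw coordinates; anisotropy or
  projection distortions are not modelled, and boundary-endpoint
  estimates rely on whatever data happen to be nearby.
* No covariates, no fuzzy assignment, no non-Gaussian likelihoods.
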
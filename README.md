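# bndd — Bayesian nonparametric discontinuity design

Gaussian-process causal inference for quasi-experimental designs in
which treatment is assigned by a threshold: regression discontinuity
(RD), interrupted time series (ITS), and two-dimensional geographic
boundaries.  Intended for epidemiologists, biostatisticians and applied
scientists who would otherwise fit two local linear regressions and test
the gap.

## The idea

Instead of estimating a jump and testing it against zero, `bndd`
compares two models of the full dataset:

* **M0 (continuous)** — one GP regression through all observations:
  `y_i ~ N(f(x_i), σ_n²)`, `f ~ GP(μ, k(x, x′; θ))`.
* **M1 (discontinuous)** — independent latent processes on the two sides
  of the threshold `x0`: the covariance is zero across the partition, so
  the Gram matrix is block-diagonal, `K = [[A, 0], [0, B]]`.

Evidence is approximated at the optimised hyperparameters `θ̂` by
`log p(D|M) ≈ log p(y|x, θ̂, M) − (l/2) log n`, and the comparison is
summarised by the log Bayes factor `log BF₁₀ = log p(D|M1) − log p(D|M0)`.
Positive values favour a discontinuity; negative values are *evidence of
absence*, which a p-value cannot express.

The effect size is reported two ways: conditional on M1 it is Gaussian,
`d | D, M1 ~ N(m, s²)` with `m` the difference of the one-sided posterior
means at `x0` and `s² = 2σ_n²` for stationary kernels; averaged over both
models it becomes a spike-and-slab distribution — a point mass at 0 with
weight `p(M0|D)` plus that Gaussian with weight `p(M1|D)` — whose mean
`p(M1|D)·m` shrinks small, uncertain effects toward zero.

The covariance function is a design choice that fixes which alternative
you test: `constant` (mean shift only — a quasi-experimental t-test),
`linear` (mean and slope), `exp` (level jumps only, the nonparametric
analogue of classical RD), `matern32` (value and first derivative),
`rbf` (discontinuities of any order), `sm` (spectral mixture, for shifts
in frequency content — the ITS workhorse).  Supplying several kernels
averages the comparison over them, weighted by their evidence.

## Worked example

Simulate an RD dataset with a true jump of `d = 2` on a linear trend
(noise σ = 1, n = 100) and analyse it:

```python
from bndd import RDSimConfig, generate_rd_dataset

data = generate_rd_dataset(RDSimConfig(function_name="linear", d=2.0,
                                       sigma=1.0, n=100, seed=7))
# write data.x / data.y to example.csv with header "x,y"
```

```bash
bndd analyze --data example.csv --mode rd --threshold 0 \
     --kernels linear,exp,matern32,rbf --seed 1 --out report.json
```

prints

```
log BF10 (total) = 4.568
p(M1 | D)        = 0.9897
effect summary   = 1.6083
BMA mean effect  = 1.5917   (spike mass 0.010)
  kernel    linear: log BF10 = +4.558
  kernel       exp: log BF10 = +4.019
  kernel  matern32: log BF10 = +4.693
  kernel       rbf: log BF10 = +4.909
report written to report.json
```

Reading: the kernel-averaged log Bayes factor of 4.6 is strong evidence
for a discontinuity (`p(M1|D) ≈ 0.99`), every candidate kernel agrees,
the jump conditional on M1 is estimated at 1.61 (true value 2, noise
σ = 1), and the model-averaged estimate 1.59 is barely shrunk because
almost no posterior mass sits on the spike at zero.  The JSON report
carries the per-kernel evidence table, the model posterior, effect
quantiles and the spike mass.

ITS analyses use the spectral-mixture kernel
(`--mode its --kernels sm`), report an effect *curve* over the
post-intervention region summarised by its largest divergence, and
geographic analyses take a boundary polyline
(`--mode geo --boundary border.csv`) and report the effect along the
border.  `bndd simulate rd|its` reruns the packaged benchmark grids into
a tidy CSV.

## Layout

```
src/bndd/kernels.py     covariance library, discontinuity mask, SM init
src/bndd/gp.py          exact GP regression, optimisation, BIC evidence
src/bndd/models.py      M0/M1 fitting, RD/ITS/geo effect sizes
src/bndd/comparison.py  Bayes factors, model posterior, spike-and-slab BMA
src/bndd/synthetic.py   simulation generators, benchmark runners, baselines
src/bndd/io.py, cli.py  data loading, orchestration, JSON reports, CLI
docs/methods.md         modelling assumptions, defaults, limitations
```
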
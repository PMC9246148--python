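"""Continuous and discontinuous GP models, and effect-size extraction.

The continuous (null) model M0 fits a single GP regression to all
observations.  The discontinuous (alternative) model M1 assumes the
latent processes before and after the threshold are independent:

* ``rd``/``geo`` mode — one shared hyperparameter set, the covariance
  masked to zero across the partition (block-diagonal Gram matrix);
* ``its`` mode — the two sides are fitted as separate GPs with their own
  hyperparameters (the intervention may change length-scale or spectral
  content, not just the level), and the joint log marginal likelihood is
  the sum of the two sides'.

Effect sizes conditional on M1:

* RD — a Gaussian N(m, s^2) for the jump at the threshold, with m the
  difference of the two one-sided posterior means evaluated at x0 and
  s^2 = 2 sigma_n^2 for stationary covariance functions;
* ITS — a curve m(x) = post-side fit minus pre-side extrapolation over
  the post region, with constant variance sigma_nA^2 + sigma_nB^2,
  summarised by the maximum absolute divergence;
* geo — the same differencing evaluated along a boundary polyline, with
  pointwise variance the sum of the two one-sided latent variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .gp import (FittedModel, GPRegression, ObservedData, OptimizerConfig,
                 fit_gp)
from .kernels import (DiscontinuousKernel, Kernel, Partition, _as_2d,
                      make_discontinuous_kernel, _StationaryKernel,
                      SpectralMixtureKernel, ConstantKernel)

__all__ = [
    "EffectSize",
    "ITSFittedModel",
    "fit_continuous",
    "fit_discontinuous",
    "rd_effect_size",
    "its_effect_curve",
    "geo_effect_curve",
    "side_posterior",
]

log = logging.getLogger("bndd")


@dataclass
class EffectSize:
    """Effect-size distribution conditional on the discontinuous model.

    ``m`` is a scalar (rd) or a curve on ``grid`` (its/geo); ``s2`` is the
    variance of the Gaussian around it; ``summary`` is the scalar headline
    number (rd: m itself; its/geo: max absolute value of the curve).
    """

    mode: str
    m: float | NDArray[np.float64]
    s2: float | NDArray[np.float64]
    grid: NDArray[np.float64] | None = None
    summary: float = 0.0
    summary_s2: float = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.s2) <= 0):
            raise ValueError("effect-size variance must be positive")


@dataclass
class ITSFittedModel:
    """Two independent per-side GPs; evidences and parameter counts add."""

    pre: FittedModel
    post: FittedModel

    @property
    def log_marginal(self) -> float:
        return self.pre.log_marginal + self.post.log_marginal

    @property
    def n_hyperparameters(self) -> int:
        return self.pre.n_hyperparameters + self.post.n_hyperparameters

    @property
    def n(self) -> int:
        return self.pre.n + self.post.n

    @property
    def bic_evidence(self) -> float:
        # the two sides have disjoint parameters and independent data, so
        # the Laplace/BIC approximation factorises: each side's penalty
        # scales with its own sample size
        return self.pre.bic_evidence + self.post.bic_evidence

    @property
    def noise_variance(self) -> float:
        return self.pre.noise_variance + self.post.noise_variance


def fit_continuous(data: ObservedData, kernel: Kernel,
                   mean_spec: str = "empirical_constant",
                   config: OptimizerConfig | None = None,
                   x0: float | None = None) -> FittedModel:
    """Fit the continuous model M0: one regression for all data points."""
    return fit_gp(data, kernel, mean=mean_spec, config=config, x0=x0)


def _split(data: ObservedData, partition: Partition):
    z = partition.labels(data.x)
    pre = ObservedData(data.x[~z], data.y[~z]) if (~z).sum() >= 2 else None
    post = ObservedData(data.x[z], data.y[z]) if z.sum() >= 2 else None
    if pre is None:
        raise ValueError("pre-threshold side has fewer than 2 observations")
    if post is None:
        raise ValueError("post-threshold side has fewer than 2 observations")
    return pre, post


def fit_discontinuous(data: ObservedData, partition: Partition, kernel: Kernel,
                      mode: str = "rd",
                      config: OptimizerConfig | None = None,
                      kernel_post: Kernel | None = None):
    """Fit the discontinuous model M1.

    ``rd``/``geo``: a single GP whose covariance is masked across the
    partition, so both blocks share one hyperparameter set theta_1 and
    the parameter count equals the continuous model's.

    ``its``: two separate GPs (hyperparameters theta_1A, theta_1B), each
    with its own empirical-mean prior; returns an :class:`ITSFittedModel`.
    """
    if mode in ("rd", "geo"):
        _split(data, partition)  # validates both sides
        masked = make_discontinuous_kernel(kernel.copy(), partition)
        fitted = fit_gp(data, masked, mean="empirical_constant", config=config)
        fitted.data.partition = partition
        return fitted
    if mode == "its":
        pre, post = _split(data, partition)
        cfg = config or OptimizerConfig()
        cfg_post = OptimizerConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        k_post = kernel_post if kernel_post is not None else kernel
        m_pre = fit_gp(pre, kernel, mean="empirical_constant", config=cfg)
        m_post = fit_gp(post, k_post, mean="empirical_constant", config=cfg_post)
        return ITSFittedModel(pre=m_pre, post=m_post)
    raise ValueError(f"unknown mode {mode!r}; expected rd, its or geo")


def side_posterior(m1: FittedModel, side: str, Xstar: ArrayLike,
                   include_noise: bool = False, full_cov: bool = False):
    """Posterior of one side's block of a shared-theta discontinuous fit.

    Because the Gram matrix is block-diagonal, each side is an independent
    GP with the shared hyperparameters conditioned on that side's data
    only; this evaluates it at arbitrary inputs (including across the
    threshold, which the masked kernel itself would zero out).
    """
    kern = m1.gp.kernel
    if not isinstance(kern, DiscontinuousKernel):
        raise ValueError("side_posterior needs a masked-kernel (rd/geo) fit")
    z = kern.partition.labels(m1.data.x)
    sel = z if side == "post" else ~z
    sub = ObservedData(m1.data.x[sel], m1.data.y[sel])
    gp_side = GPRegression(kern.base, m1.gp.mean, m1.gp.noise_variance)
    return gp_side.predict(sub, Xstar, include_noise=include_noise,
                           full_cov=full_cov)


def rd_effect_size(m1: FittedModel, x0: float,
                   use_predictive_variance: bool = False) -> EffectSize:
    """Gaussian effect size N(m, s^2) at the threshold for an RD fit.

    m is the post-side minus pre-side posterior mean, both blocks
    evaluated exactly at x0 (the GP posterior mean is continuous, so the
    one-sided limits equal the values).  For stationary kernels
    s^2 = 2 sigma_n^2; for non-stationary kernels — or on request — the
    two one-sided latent predictive variances at x0 are summed instead.
    """
    xstar = np.array([[float(x0)]])
    mean_pre, var_pre = side_posterior(m1, "pre", xstar)
    mean_post, var_post = side_posterior(m1, "post", xstar)
    m = float(mean_post[0] - mean_pre[0])

    base = m1.gp.kernel.base
    stationary = isinstance(base, (_StationaryKernel, SpectralMixtureKernel,
                                   ConstantKernel))
    if use_predictive_variance or not stationary:
        if not stationary:
            log.info("non-stationary kernel: effect variance from one-sided "
                     "posterior predictive variances instead of 2*sigma_n^2")
        s2 = float(var_pre[0] + var_post[0] + 2 * m1.noise_variance) \
            if use_predictive_variance else float(var_pre[0] + var_post[0])
    else:
        s2 = 2.0 * m1.noise_variance
    return EffectSize(mode="rd", m=m, s2=s2, summary=m, summary_s2=s2)


def its_effect_curve(m1: ITSFittedModel, x_grid: ArrayLike) -> EffectSize:
    """Effect curve m(x) over the post region for an ITS fit.

    m(x) = (post-side posterior mean) - (pre-side extrapolated posterior
    mean) on the grid; the variance sigma_nA^2 + sigma_nB^2 is constant in
    x.  The curve is summarised by its maximum absolute value.
    """
    grid = np.asarray(x_grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("ITS effect grid is empty")
    Xg = grid[:, None]
    mean_pre, _ = m1.pre.predict(Xg)
    mean_post, _ = m1.post.predict(Xg)
    curve = mean_post - mean_pre
    s2 = m1.pre.noise_variance + m1.post.noise_variance
    i = int(np.argmax(np.abs(curve)))
    return EffectSize(mode="its", m=curve, s2=s2, grid=grid,
                      summary=float(curve[i]), summary_s2=s2)


def geo_effect_curve(m1: FittedModel, boundary_points: ArrayLike) -> EffectSize:
    """Effect curve d(s) along a 2-D boundary for a geo-mode fit.

    At each boundary point the post-side and pre-side blocks both predict
    (labels are irrelevant for prediction), and d(s) is their difference
    with pointwise variance the sum of the two latent variances.
    """
    S = _as_2d(boundary_points)
    if S.shape[1] != 2:
        raise ValueError("boundary points must be 2-D coordinates")
    mean_pre, var_pre = side_posterior(m1, "pre", S)
    mean_post, var_post = side_posterior(m1, "post", S)
    curve = mean_post - mean_pre
    s2 = np.maximum(var_pre + var_post, 1e-12)
    i = int(np.argmax(np.abs(curve)))
    return EffectSize(mode="geo", m=curve, s2=s2, grid=S,
                      summary=float(curve[i]), summary_s2=float(s2[i]))


def arc_length_samples(boundary: ArrayLike, n: int = 100) -> NDArray[np.float64]:
    """Arc-length-uniform points along a polyline, for geo effect curves."""
    V = _as_2d(boundary)
    seg = np.diff(V, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(s, cum, V[:, d])
    return out
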
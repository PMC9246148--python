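"""Exact Gaussian-process regression with Gaussian observation noise.

Provides the closed-form log marginal likelihood, multi-restart
quasi-Newton hyperparameter optimisation with analytic gradients,
posterior prediction, and the BIC approximation to the model evidence

    log p(D | M) ~= log p(y | x, theta_hat, M) - (l/2) log n,

with l the number of optimised hyperparameters.  Natural logarithms are
used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit

from .kernels import Kernel, _as_2d, softplus, softplus_inverse

__all__ = [
    "ObservedData",
    "MeanFunction",
    "ConstantMean",
    "ChangepointConstantMean",
    "GPRegression",
    "FittedModel",
    "log_marginal_likelihood",
    "fit_gp",
    "bic_evidence",
    "OptimizerConfig",
]

JITTER_SCALE = 1e-6  # times the mean Gram diagonal (signal variance)


@dataclass
class ObservedData:
    """Inputs x (n x d), responses y (n,), and an optional partition."""

    x: NDArray[np.float64]
    y: NDArray[np.float64]
    partition: object | None = None

    def __post_init__(self):
        self.x = _as_2d(self.x)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape[0] != self.y.size:
            raise ValueError("x and y must have the same length")
        if self.y.size < 2:
            raise ValueError("need at least 2 observations")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("responses must be finite")

    @property
    def n(self) -> int:
        return self.y.size


# ---------------------------------------------------------------------------
# Mean functions
# ---------------------------------------------------------------------------

class MeanFunction:
    """Prior mean mu(x).  Parameters, if any, are optimised with the kernel."""

    n_params = 0

    def __call__(self, X: ArrayLike) -> NDArray[np.float64]:
        raise NotImplementedError

    def gradients(self, X: ArrayLike) -> list[NDArray[np.float64]]:
        return []

    def get_unconstrained(self) -> NDArray[np.float64]:
        return np.empty(0)

    def set_unconstrained(self, u: ArrayLike) -> None:
        if np.asarray(u).size:
            raise ValueError("mean function has no free parameters")

    def copy(self) -> "MeanFunction":
        import copy as _copy

        return _copy.deepcopy(self)


class ConstantMean(MeanFunction):
    """Fixed constant mean, by convention the empirical mean of y (not optimised)."""

    def __init__(self, value: float = 0.0):
        self.value = float(value)

    def __call__(self, X):
        X = _as_2d(X)
        return np.full(X.shape[0], self.value)


class ChangepointConstantMean(MeanFunction):
    """Sigmoid blend of two constants around x0, with fixed steepness.

    mu(x) = c_pre + (c_post - c_pre) * sigmoid(steepness * (x - x0))

    Both constants are free parameters (counted towards the BIC penalty);
    the steepness is fixed so the transition acts as a step on the scale
    of the data.  Used as the continuous-model mean when a level shift is
    not itself the effect of interest (e.g. heart-rate fluctuation
    analyses).
    """

    n_params = 2

    def __init__(self, c_pre: float, c_post: float, x0: float, steepness: float = 50.0):
        self.c_pre = float(c_pre)
        self.c_post = float(c_post)
        self.x0 = float(x0)
        self.steepness = float(steepness)

    def _blend(self, X):
        X = _as_2d(X)
        return expit(self.steepness * (X[:, 0] - self.x0))

    def __call__(self, X):
        s = self._blend(X)
        return self.c_pre + (self.c_post - self.c_pre) * s

    def gradients(self, X):
        s = self._blend(X)
        return [1.0 - s, s]

    def get_unconstrained(self):
        return np.array([self.c_pre, self.c_post])

    def set_unconstrained(self, u):
        u = np.asarray(u, dtype=float)
        if u.size != 2:
            raise ValueError("expected 2 mean parameters")
        self.c_pre, self.c_post = float(u[0]), float(u[1])


def make_mean(mean_spec: str, y: NDArray[np.float64], x: NDArray[np.float64],
              x0: float | None = None) -> MeanFunction:
    """Resolve a mean-spec name against the data."""
    if mean_spec == "empirical_constant":
        return ConstantMean(float(np.mean(y)))
    if mean_spec == "zero":
        return ConstantMean(0.0)
    if mean_spec == "changepoint_constant":
        if x0 is None:
            raise ValueError("changepoint_constant mean needs a threshold x0")
        x1 = _as_2d(x)[:, 0]
        pre, post = y[x1 < x0], y[x1 >= x0]
        c_pre = float(pre.mean()) if pre.size else float(y.mean())
        c_post = float(post.mean()) if post.size else float(y.mean())
        rng_x = np.ptp(x1) or 1.0
        return ChangepointConstantMean(c_pre, c_post, x0, steepness=100.0 / rng_x)
    raise ValueError(f"unknown mean_spec {mean_spec!r}")


# ---------------------------------------------------------------------------
# The GP model
# ---------------------------------------------------------------------------

class GPRegression:
    """y ~ N(mu(x), K + sigma_n^2 I) with K from the kernel.

    The free-parameter vector is [kernel params, mean params, log-scale
    noise variance], all on the unconstrained (softplus) scale.
    """

    def __init__(self, kernel: Kernel, mean: MeanFunction, noise_variance: float = 0.1):
        if noise_variance <= 0:
            raise ValueError("noise variance must be > 0")
        self.kernel = kernel
        self.mean = mean
        self.noise_variance = float(noise_variance)

    # -- parameter vector ---------------------------------------------------

    @property
    def n_params(self) -> int:
        """Number of optimised hyperparameters (kernel + mean + noise)."""
        return self.kernel.n_params + self.mean.n_params + 1

    def get_unconstrained(self) -> NDArray[np.float64]:
        return np.concatenate([
            self.kernel.get_unconstrained(),
            self.mean.get_unconstrained(),
            np.atleast_1d(softplus_inverse(self.noise_variance)),
        ])

    def set_unconstrained(self, u: ArrayLike) -> None:
        u = np.asarray(u, dtype=float)
        nk = self.kernel.n_params
        nm = self.mean.n_params
        self.kernel.set_unconstrained(u[:nk])
        self.mean.set_unconstrained(u[nk : nk + nm])
        self.noise_variance = float(softplus(u[-1]))

    def copy(self) -> "GPRegression":
        return GPRegression(self.kernel.copy(), self.mean.copy(), self.noise_variance)

    # -- likelihood ---------------------------------------------------------

    def _gram_chol(self, X):
        K = self.kernel(X)
        jitter = JITTER_SCALE * max(float(np.mean(np.diag(K))), 1e-12)
        Ky = K + (self.noise_variance + jitter) * np.eye(K.shape[0])
        for bump in range(6):
            try:
                L = cholesky(Ky, lower=True)
                return K, Ky, L
            except np.linalg.LinAlgError:
                extra = jitter * 10 ** (bump + 1)
                Ky = K + (self.noise_variance + extra) * np.eye(K.shape[0])
        raise np.linalg.LinAlgError(
            "Gram matrix not positive definite after jitter escalation; "
            f"kernel={type(self.kernel).__name__}, noise={self.noise_variance:.3g}"
        )

    def log_marginal(self, data: ObservedData) -> float:
        X, y = data.x, data.y
        _, _, L = self._gram_chol(X)
        r = y - self.mean(X)
        alpha = solve_triangular(L, r, lower=True)
        return float(
            -0.5 * alpha @ alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * y.size * np.log(2 * np.pi)
        )

    def log_marginal_and_grad(self, data: ObservedData) -> tuple[float, NDArray]:
        """Value and gradient w.r.t. the unconstrained parameter vector."""
        X, y = data.x, data.y
        n = y.size
        _, _, L = self._gram_chol(X)
        r = y - self.mean(X)
        a = solve_triangular(L, r, lower=True)
        lml = float(-0.5 * a @ a - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi))

        alpha = cho_solve((L, True), r)
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv  # dL/dK = W/2

        grads = []
        for dK in self.kernel.gradients(X):
            grads.append(0.5 * float(np.sum(W * dK)))
        for dmu in self.mean.gradients(X):
            grads.append(float(dmu @ alpha))
        grads.append(0.5 * float(np.trace(W)))  # dK/dsigma_n^2 = I
        grad_c = np.asarray(grads)

        # chain rule onto the unconstrained scale
        jac = np.concatenate([
            self.kernel.unconstrained_jacobian(),
            np.ones(self.mean.n_params),
            np.atleast_1d(expit(softplus_inverse(self.noise_variance))),
        ])
        return lml, grad_c * jac

    # -- prediction ---------------------------------------------------------

    def predict(self, data: ObservedData, Xstar: ArrayLike,
                include_noise: bool = False, full_cov: bool = False):
        """Posterior mean and (co)variance of the latent f at Xstar."""
        X, y = data.x, data.y
        Xstar = _as_2d(Xstar)
        if Xstar.shape[1] != X.shape[1]:
            raise ValueError("prediction inputs have wrong dimensionality")
        _, _, L = self._gram_chol(X)
        r = y - self.mean(X)
        alpha = cho_solve((L, True), r)
        Ks = self.kernel(X, Xstar)  # (n, m)
        mean = self.mean(Xstar) + Ks.T @ alpha
        V = solve_triangular(L, Ks, lower=True)
        if full_cov:
            cov = self.kernel(Xstar) - V.T @ V
            if include_noise:
                cov = cov + self.noise_variance * np.eye(cov.shape[0])
            return mean, cov
        var = self.kernel.diag(Xstar) - np.sum(V**2, axis=0)
        var = np.maximum(var, 0.0)
        if include_noise:
            var = var + self.noise_variance
        return mean, var


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    n_restarts: int = 10
    seed: int = 0
    maxiter: int = 200
    lengthscale_init_range: tuple[float, float] = (0.1, 2.0)  # times range of x
    sm_jitter_sd: float = 0.3  # lognormal sd for SM restart perturbations


@dataclass
class FittedModel:
    """A GP with optimised hyperparameters and its evidence approximation."""

    gp: GPRegression
    data: ObservedData
    log_marginal: float
    n_hyperparameters: int
    mean_spec: str = "empirical_constant"
    converged: bool = True
    restart_history: list = field(default_factory=list, repr=False)

    @property
    def noise_variance(self) -> float:
        return self.gp.noise_variance

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def bic_evidence(self) -> float:
        return bic_evidence(self)

    def predict(self, Xstar, include_noise: bool = False, full_cov: bool = False):
        return self.gp.predict(self.data, Xstar, include_noise=include_noise,
                               full_cov=full_cov)


def log_marginal_likelihood(data: ObservedData, kernel: Kernel,
                            mean: MeanFunction | None = None,
                            noise_variance: float = 0.1) -> float:
    """Closed-form log N(y | mu(x), K + sigma_n^2 I) via Cholesky."""
    mean = mean if mean is not None else ConstantMean(float(np.mean(data.y)))
    return GPRegression(kernel, mean, noise_variance).log_marginal(data)


def bic_evidence(model: FittedModel, n: int | None = None) -> float:
    """log evidence ~= log marginal at theta_hat minus (l/2) log n."""
    n = model.n if n is None else int(n)
    if n < 2:
        raise ValueError("BIC evidence needs n >= 2")
    return model.log_marginal - 0.5 * model.n_hyperparameters * np.log(n)


def _random_restart(gp: GPRegression, data: ObservedData, rng: np.random.Generator,
                    cfg: OptimizerConfig) -> NDArray[np.float64]:
    """Draw an initial unconstrained vector for one restart."""
    from .kernels import (DiscontinuousKernel, LinearKernel,
                          SpectralMixtureKernel, _StationaryKernel)

    g = gp.copy()
    kern = g.kernel.base if isinstance(g.kernel, DiscontinuousKernel) else g.kernel
    x_range = float(np.ptp(data.x[:, 0])) or 1.0
    var_y = float(np.var(data.y)) or 1.0
    lo, hi = cfg.lengthscale_init_range

    if isinstance(kern, _StationaryKernel):
        ell = x_range * np.exp(rng.uniform(np.log(lo), np.log(hi)))
        kern._values[0][:] = var_y
        kern._values[1][:] = ell
    elif isinstance(kern, LinearKernel):
        var_x = float(np.var(data.x[:, 0])) or 1.0
        kern._values[0][:] = var_y / var_x * np.exp(rng.normal(0, 1))
        kern._values[1][:] = np.mean(data.x, axis=0)
        kern._values[2][:] = var_y * np.exp(rng.normal(0, 1))
    elif isinstance(kern, SpectralMixtureKernel):
        for v in kern._values:
            v *= np.exp(rng.normal(0.0, cfg.sm_jitter_sd, size=v.size))
    else:  # constant: rescale the variance
        kern._values[0][:] = var_y * np.exp(rng.normal(0, 1))
    g.noise_variance = 0.1 * var_y * np.exp(rng.normal(0, 0.5))
    if isinstance(g.kernel, DiscontinuousKernel):
        g.kernel.set_unconstrained(kern.get_unconstrained())
    return g.get_unconstrained()


def fit_gp(data: ObservedData, kernel: Kernel,
           mean: MeanFunction | str | None = None,
           noise_variance: float | None = None,
           config: OptimizerConfig | None = None,
           x0: float | None = None) -> FittedModel:
    """Maximise the log marginal likelihood over hyperparameters.

    Multi-restart L-BFGS with analytic gradients on the softplus
    (unconstrained) scale.  The first restart starts from the kernel's
    current parameters — for the spectral mixture that is the
    periodogram/GMM initialisation — and subsequent restarts draw fresh
    initial points from the data-driven scheme.  Deterministic given the
    seed in ``config``.
    """
    cfg = config or OptimizerConfig()
    if isinstance(mean, str) or mean is None:
        mean_spec = mean or "empirical_constant"
        mean = make_mean(mean_spec, data.y, data.x, x0=x0)
    else:
        mean_spec = type(mean).__name__
    if noise_variance is None:
        noise_variance = 0.1 * float(np.var(data.y)) or 0.1
    gp = GPRegression(kernel.copy(), mean, noise_variance)
    rng = np.random.default_rng(cfg.seed)

    def objective(u):
        gp.set_unconstrained(u)
        try:
            lml, grad = gp.log_marginal_and_grad(data)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            # overflowing hyperparameters can poison the Gram matrix with
            # non-finite entries; treat the point as infeasible
            return 1e12, np.zeros_like(u)
        if not np.isfinite(lml):
            return 1e12, np.zeros_like(u)
        return -lml, -grad

    best_u, best_lml = None, -np.inf
    history = []
    any_converged = False
    for restart in range(max(cfg.n_restarts, 1)):
        if restart == 0:
            u0 = gp.get_unconstrained()
        else:
            u0 = _random_restart(gp, data, rng, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                           options={"maxiter": cfg.maxiter})
        lml = -res.fun if np.isfinite(res.fun) and res.fun < 1e11 else -np.inf
        init_lml = -objective(u0)[0]
        if init_lml > -1e11 and lml < init_lml:  # never accept a downhill step
            lml, res = init_lml, None
            u_opt = u0
        else:
            u_opt = res.x
        history.append({"init": init_lml, "final": lml})
        # status 1 is the iteration cap: a usable optimum, not a failure
        any_converged = any_converged or (
            res is not None and (res.success or res.status == 1))
        if lml > best_lml:
            best_lml, best_u = lml, u_opt.copy()

    if best_u is None or not np.isfinite(best_lml):
        raise np.linalg.LinAlgError("all optimisation restarts failed")
    if not any_converged:
        warnings.warn("no optimiser restart reported convergence; "
                      "returning best evaluated point", RuntimeWarning)
    gp.set_unconstrained(best_u)
    lml = gp.log_marginal(data)
    return FittedModel(gp=gp, data=data, log_marginal=lml,
                       n_hyperparameters=gp.n_params, mean_spec=mean_spec,
                       converged=any_converged, restart_history=history)
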
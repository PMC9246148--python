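"""Covariance functions for discontinuity-design Gaussian processes.

The library covers the kernel families used in quasi-experimental GP
regression: degenerate kernels that replicate parametric regressions
(constant, linear), the Matern family for discontinuities up to a given
derivative order (exponential = Matern-1/2, Matern-3/2, and the
exponentiated quadratic as the smooth limit), and the spectral mixture
kernel for quasi-periodic series.  A masking wrapper zeroes covariance
across a threshold partition, which makes the Gram matrix block-diagonal
and the pre/post processes independent: the discontinuous model.

Hyperparameters that must stay positive are stored internally on an
unconstrained scale through a softplus bijection, so that gradient-based
optimisers can move freely.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.signal import lombscargle
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.mixture import GaussianMixture

__all__ = [
    "Kernel",
    "ConstantKernel",
    "LinearKernel",
    "ExponentialKernel",
    "Matern32Kernel",
    "RBFKernel",
    "SpectralMixtureKernel",
    "DiscontinuousKernel",
    "Partition",
    "make_kernel",
    "make_discontinuous_kernel",
    "init_spectral_mixture",
    "lomb_scargle_spectrum",
    "softplus",
    "softplus_inverse",
    "KERNEL_NAMES",
]

_SOFTPLUS_FLOOR = 1e-10


def softplus(u: ArrayLike) -> NDArray[np.float64]:
    """Map unconstrained reals to positive reals, log(1 + e^u)."""
    return np.logaddexp(0.0, np.asarray(u, dtype=float))


def softplus_inverse(v: ArrayLike) -> NDArray[np.float64]:
    v = np.maximum(np.asarray(v, dtype=float), _SOFTPLUS_FLOOR)
    # u = v + log(1 - e^{-v}), stable for both small and large v
    return v + np.log(-np.expm1(-v))


def _as_2d(X: ArrayLike) -> NDArray[np.float64]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"inputs must be 1-D or 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    return X


class Kernel:
    """Base class: a parametrised covariance function k(x, x'; theta).

    Subclasses define ``param_names``, a matching tuple ``param_positive``
    of positivity flags, compute the Gram matrix in :meth:`__call__` and
    its per-parameter derivatives in :meth:`gradients`.
    """

    param_names: tuple[str, ...] = ()
    param_positive: tuple[bool, ...] = ()

    def __init__(self, **params: float):
        values = []
        for name, pos in zip(self.param_names, self.param_positive):
            v = np.atleast_1d(np.asarray(params[name], dtype=float))
            if pos and np.any(v <= 0):
                raise ValueError(f"{type(self).__name__}: {name} must be > 0, got {v}")
            values.append(v)
        self._values = values

    # -- parameter plumbing -------------------------------------------------

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self._values))

    def get_params(self) -> dict[str, NDArray[np.float64]]:
        return {n: v.copy() for n, v in zip(self.param_names, self._values)}

    def __getitem__(self, name: str) -> NDArray[np.float64]:
        return self._values[self.param_names.index(name)]

    def get_unconstrained(self) -> NDArray[np.float64]:
        out = []
        for v, pos in zip(self._values, self.param_positive):
            out.append(softplus_inverse(v) if pos else v)
        return np.concatenate(out)

    def set_unconstrained(self, u: ArrayLike) -> None:
        u = np.asarray(u, dtype=float)
        i = 0
        for j, (v, pos) in enumerate(zip(self._values, self.param_positive)):
            chunk = u[i : i + v.size]
            self._values[j] = softplus(chunk) if pos else chunk.copy()
            i += v.size
        if i != u.size:
            raise ValueError("unconstrained vector has wrong length")

    def unconstrained_jacobian(self) -> NDArray[np.float64]:
        """d(constrained)/d(unconstrained), elementwise (diagonal chain rule)."""
        out = []
        for v, pos in zip(self._values, self.param_positive):
            if pos:
                out.append(expit(softplus_inverse(v)))
            else:
                out.append(np.ones_like(v))
        return np.concatenate(out)

    def copy(self) -> "Kernel":
        k = object.__new__(type(self))
        k.__dict__.update(self.__dict__)
        k._values = [v.copy() for v in self._values]
        return k

    # -- evaluation ---------------------------------------------------------

    def __call__(self, X: ArrayLike, X2: ArrayLike | None = None) -> NDArray[np.float64]:
        raise NotImplementedError

    def diag(self, X: ArrayLike) -> NDArray[np.float64]:
        X = _as_2d(X)
        return np.diag(self(X, X)).copy()

    def gradients(self, X: ArrayLike) -> list[NDArray[np.float64]]:
        """dK/d(theta_i) on the constrained scale, one matrix per scalar."""
        raise NotImplementedError

    def _check_pair(self, X, X2):
        X = _as_2d(X)
        X2 = X if X2 is None else _as_2d(X2)
        if X.shape[1] != X2.shape[1]:
            raise ValueError(
                f"input dimensionality mismatch: {X.shape[1]} vs {X2.shape[1]}"
            )
        return X, X2


class ConstantKernel(Kernel):
    """k(x, x') = variance.  Sensitive only to a mean difference."""

    param_names = ("variance",)
    param_positive = (True,)

    def __init__(self, variance: float = 1.0):
        super().__init__(variance=variance)

    def __call__(self, X, X2=None):
        X, X2 = self._check_pair(X, X2)
        return np.full((X.shape[0], X2.shape[0]), float(self["variance"][0]))

    def gradients(self, X):
        X = _as_2d(X)
        return [np.ones((X.shape[0], X.shape[0]))]


class LinearKernel(Kernel):
    """k(x, x') = variance * (x - offset) . (x' - offset) + bias.

    The learnable offset and bias let the induced regression represent an
    arbitrary intercept and slope, the nonparametric stand-in for linear
    regression discontinuity.
    """

    param_names = ("variance", "offset", "bias")
    param_positive = (True, False, True)

    def __init__(self, variance=1.0, offset=0.0, bias=1.0, input_dim=1):
        offset = np.broadcast_to(np.asarray(offset, dtype=float), (input_dim,)).copy()
        super().__init__(variance=variance, offset=offset, bias=bias)

    def __call__(self, X, X2=None):
        X, X2 = self._check_pair(X, X2)
        c = self["offset"]
        return float(self["variance"][0]) * (X - c) @ (X2 - c).T + float(self["bias"][0])

    def gradients(self, X):
        X = _as_2d(X)
        c = self["offset"]
        v = float(self["variance"][0])
        Xc = X - c
        grads = [Xc @ Xc.T]
        for j in range(c.size):
            col = Xc[:, j]
            grads.append(-v * (col[:, None] + col[None, :]))
        grads.append(np.ones((X.shape[0], X.shape[0])))
        return grads


class _StationaryKernel(Kernel):
    """Isotropic kernels of the Euclidean distance r = |x - x'|."""

    param_names = ("variance", "lengthscale")
    param_positive = (True, True)

    def __init__(self, variance=1.0, lengthscale=1.0):
        super().__init__(variance=variance, lengthscale=lengthscale)

    def _r(self, X, X2):
        return cdist(X, X2)

    def __call__(self, X, X2=None):
        X, X2 = self._check_pair(X, X2)
        return self._value(self._r(X, X2))

    def _value(self, r):
        raise NotImplementedError


class ExponentialKernel(_StationaryKernel):
    """Matern with nu = 1/2: detects level discontinuities only (Markov)."""

    def _value(self, r):
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        return v * np.exp(-r / l)

    def gradients(self, X):
        X = _as_2d(X)
        r = self._r(X, X)
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        E = np.exp(-r / l)
        return [E, v * E * r / l**2]


class Matern32Kernel(_StationaryKernel):
    """Matern with nu = 3/2: sensitive to jumps in value and first derivative."""

    def _value(self, r):
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        a = np.sqrt(3.0) * r / l
        return v * (1.0 + a) * np.exp(-a)

    def gradients(self, X):
        X = _as_2d(X)
        r = self._r(X, X)
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        a = np.sqrt(3.0) * r / l
        E = np.exp(-a)
        return [(1.0 + a) * E, v * a**2 * E / l]


class RBFKernel(_StationaryKernel):
    """Exponentiated quadratic (Matern nu -> inf): discontinuities of any order."""

    def _value(self, r):
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        return v * np.exp(-0.5 * (r / l) ** 2)

    def gradients(self, X):
        X = _as_2d(X)
        r = self._r(X, X)
        v, l = float(self["variance"][0]), float(self["lengthscale"][0])
        K = v * np.exp(-0.5 * (r / l) ** 2)
        return [K / v, K * r**2 / l**3]


class SpectralMixtureKernel(Kernel):
    """Stationary kernel whose spectral density is a Q-component Gaussian mixture.

    k(tau) = sum_q w_q cos(2 pi tau mu_q) exp(-2 pi^2 tau^2 sigma_q^2)

    with tau = |x - x'|.  mu_q is the centre frequency of component q in
    cycles per unit of x, 1/sigma_q acts as the length-scale over which
    that frequency's contribution decorrelates, and w_q is its variance
    contribution, so k(0) = sum_q w_q.  Long, coherent oscillations
    (narrow spectral peaks, small sigma_q) make this kernel extrapolate
    far beyond the data — the property that matters for interrupted time
    series.  One-dimensional inputs only.
    """

    param_names = ("weights", "means", "scales")
    param_positive = (True, True, True)

    def __init__(self, weights, means, scales):
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        means = np.atleast_1d(np.asarray(means, dtype=float))
        scales = np.atleast_1d(np.asarray(scales, dtype=float))
        if weights.size == 0:
            raise ValueError("spectral mixture needs at least one component (Q >= 1)")
        if not (weights.size == means.size == scales.size):
            raise ValueError("weights, means and scales must all have length Q")
        # zero/negative mean frequencies are valid spectra (DC component) but the
        # softplus bijection needs strictly positive values; clamp to a tiny floor.
        means = np.maximum(means, 1e-8)
        weights = np.maximum(weights, 1e-8)
        super().__init__(weights=weights, means=means, scales=scales)

    @property
    def Q(self) -> int:
        return self["weights"].size

    @staticmethod
    def value(tau: ArrayLike, weights, means, scales) -> NDArray[np.float64]:
        """Evaluate k(tau) for given mixture parameters (tau >= 0)."""
        tau = np.asarray(tau, dtype=float)
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        mu = np.atleast_1d(np.asarray(means, dtype=float))
        s = np.atleast_1d(np.asarray(scales, dtype=float))
        if w.size == 0:
            raise ValueError("Q must be >= 1")
        t = tau[..., None]
        terms = w * np.cos(2 * np.pi * t * mu) * np.exp(-2 * np.pi**2 * t**2 * s**2)
        return terms.sum(axis=-1)

    def __call__(self, X, X2=None):
        X, X2 = self._check_pair(X, X2)
        if X.shape[1] != 1:
            raise ValueError("spectral mixture kernel supports 1-D inputs only")
        tau = np.abs(X - X2.T)
        return self.value(tau, self["weights"], self["means"], self["scales"])

    def gradients(self, X):
        X = _as_2d(X)
        tau = np.abs(X - X.T)
        w, mu, s = self["weights"], self["means"], self["scales"]
        grads_w, grads_mu, grads_s = [], [], []
        for q in range(self.Q):
            cosq = np.cos(2 * np.pi * tau * mu[q])
            sinq = np.sin(2 * np.pi * tau * mu[q])
            decq = np.exp(-2 * np.pi**2 * tau**2 * s[q] ** 2)
            grads_w.append(cosq * decq)
            grads_mu.append(-w[q] * 2 * np.pi * tau * sinq * decq)
            grads_s.append(-w[q] * cosq * decq * 4 * np.pi**2 * tau**2 * s[q])
        return grads_w + grads_mu + grads_s

    def spectral_density(self, freq: ArrayLike) -> NDArray[np.float64]:
        """Two-sided spectral density S(omega) at frequencies in cycles/unit."""
        freq = np.asarray(freq, dtype=float)[..., None]
        w, mu, s = self["weights"], self["means"], self["scales"]
        comp = w / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((freq - mu) / s) ** 2)
        return comp.sum(axis=-1)


class Partition:
    """Assigns observations to the pre/post side of a threshold.

    In one dimension the rule is: post (treated) iff x >= x0, so the
    boundary point itself belongs to the post side.  In two dimensions the
    side is the sign of the cross product against the nearest segment of a
    boundary polyline, with vertices given in order.
    """

    def __init__(self, threshold: float | None = None,
                 boundary: ArrayLike | None = None):
        if (threshold is None) == (boundary is None):
            raise ValueError("give exactly one of threshold (1-D) or boundary (2-D)")
        self.threshold = None if threshold is None else float(threshold)
        self.boundary = None if boundary is None else _as_2d(boundary)
        if self.boundary is not None and self.boundary.shape[0] < 2:
            raise ValueError("boundary polyline needs at least two vertices")

    def labels(self, X: ArrayLike) -> NDArray[np.bool_]:
        """True for post/treated-side points."""
        X = _as_2d(X)
        if self.threshold is not None:
            return X[:, 0] >= self.threshold
        return self._polyline_side(X) >= 0

    def _polyline_side(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        V = self.boundary
        A, B = V[:-1], V[1:]  # (m, 2) segment endpoints
        AB = B - A
        seg_len2 = np.maximum((AB**2).sum(axis=1), 1e-300)
        AP = X[:, None, :] - A[None, :, :]  # (n, m, 2)
        t = np.clip((AP * AB).sum(axis=2) / seg_len2, 0.0, 1.0)
        proj = A[None, :, :] + t[:, :, None] * AB[None, :, :]
        d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        ab = AB[nearest]
        ap = X - A[nearest]
        return ab[:, 0] * ap[:, 1] - ab[:, 1] * ap[:, 0]


class DiscontinuousKernel(Kernel):
    """Masking wrapper: base covariance on the same side of the partition, 0 across.

    On side-sorted inputs the Gram matrix is block-diagonal, so the latent
    processes before and after the threshold are independent while sharing
    one hyperparameter set.
    """

    def __init__(self, base: Kernel, partition: Partition):
        self.base = base
        self.partition = partition
        self._values = base._values  # shared storage: one theta

    @property
    def param_names(self):  # type: ignore[override]
        return self.base.param_names

    @property
    def param_positive(self):  # type: ignore[override]
        return self.base.param_positive

    def _mask(self, X, X2):
        z1 = self.partition.labels(X)
        z2 = self.partition.labels(X2)
        return (z1[:, None] == z2[None, :]).astype(float)

    def __call__(self, X, X2=None):
        X, X2 = self._check_pair(X, X2)
        return self.base(X, X2) * self._mask(X, X2)

    def gradients(self, X):
        X = _as_2d(X)
        M = self._mask(X, X)
        return [g * M for g in self.base.gradients(X)]

    def copy(self) -> "DiscontinuousKernel":
        return DiscontinuousKernel(self.base.copy(), self.partition)

    # parameter plumbing must flow through to the shared base storage
    def get_unconstrained(self):
        return self.base.get_unconstrained()

    def set_unconstrained(self, u):
        self.base.set_unconstrained(u)
        self._values = self.base._values

    def unconstrained_jacobian(self):
        return self.base.unconstrained_jacobian()

    def get_params(self):
        return self.base.get_params()

    def __getitem__(self, name):
        return self.base[name]

    @property
    def n_params(self):
        return self.base.n_params


def make_discontinuous_kernel(base: Kernel, partition: Partition) -> DiscontinuousKernel:
    return DiscontinuousKernel(base, partition)


# ---------------------------------------------------------------------------
# Spectral mixture initialisation from the empirical spectrum
# ---------------------------------------------------------------------------

def lomb_scargle_spectrum(
    x: ArrayLike,
    y: ArrayLike,
    n_freq: int = 5000,
    f_max: float | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Lomb-Scargle periodogram of (x, y) on a regular frequency grid.

    Valid for unevenly sampled series.  Frequencies are in cycles per unit
    of x; the upper limit defaults to the pseudo-Nyquist rate
    1 / (2 * median spacing).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("need at least 8 observations for a spectrum")
    xs = np.sort(x)
    spacing = np.median(np.diff(xs))
    if spacing <= 0:
        raise ValueError("x values must not all be identical")
    if f_max is None:
        f_max = 1.0 / (2.0 * spacing)
    freqs = np.linspace(f_max / n_freq, f_max, n_freq)
    # deliberately uncentred: a constant offset shows up as power at the
    # lowest frequencies, so near-constant signals initialise to a DC-like
    # (mean-difference) component rather than to an arbitrary frequency
    power = lombscargle(x, y, 2 * np.pi * freqs, normalize=False)
    return freqs, power


def init_spectral_mixture(
    x: ArrayLike,
    y: ArrayLike,
    Q: int,
    seed: int = 0,
    n_freq: int = 5000,
) -> SpectralMixtureKernel:
    """Initialise SM parameters from the empirical spectrum.

    Fits a Q-component Gaussian mixture to the Lomb-Scargle periodogram,
    treated as an (unnormalised) density over frequency; component means
    and standard deviations become the mixture frequencies and scales, and
    the mixture weights are rescaled so that k(0) equals the sample
    variance of y.  Deterministic given the seed.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    freqs, power = lomb_scargle_spectrum(x, y, n_freq=n_freq)
    # broadband observation noise adds a roughly flat floor to the
    # periodogram; subtract a high quantile and square what remains so the
    # mixture latches onto pronounced spectral peaks, not floor or sidelobes
    p = np.maximum(power - np.quantile(power, 0.95), 0.0) ** 2
    if p.sum() <= 0:
        p = np.maximum(power, 0.0)
    if p.sum() <= 0:
        p = np.ones_like(p)
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    draws = rng.choice(freqs, size=20000, replace=True, p=p)
    # jitter within a grid bin so the GMM does not see atoms
    bin_width = freqs[1] - freqs[0]
    draws = draws + rng.uniform(-0.5, 0.5, size=draws.size) * bin_width

    gmm = GaussianMixture(
        n_components=Q,
        covariance_type="diag",
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_init=3,
        reg_covar=(bin_width / 2) ** 2,
    )
    gmm.fit(draws[:, None])
    means = np.maximum(gmm.means_.ravel(), 0.0)
    scales = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel() * max(y.var(), 1e-12)

    order = np.argsort(-weights)
    return SpectralMixtureKernel(weights[order], means[order], scales[order])


KERNEL_NAMES = ("constant", "linear", "exp", "matern32", "rbf", "sm")


def make_kernel(name: str, input_dim: int = 1, **kwargs) -> Kernel:
    """Build a kernel by its config-file name."""
    name = name.lower()
    if name == "constant":
        return ConstantKernel(variance=kwargs.get("variance", 1.0))
    if name == "linear":
        return LinearKernel(
            variance=kwargs.get("variance", 1.0),
            offset=kwargs.get("offset", 0.0),
            bias=kwargs.get("bias", 1.0),
            input_dim=input_dim,
        )
    if name == "exp":
        return ExponentialKernel(
            variance=kwargs.get("variance", 1.0),
            lengthscale=kwargs.get("lengthscale", 1.0),
        )
    if name == "matern32":
        return Matern32Kernel(
            variance=kwargs.get("variance", 1.0),
            lengthscale=kwargs.get("lengthscale", 1.0),
        )
    if name == "rbf":
        return RBFKernel(
            variance=kwargs.get("variance", 1.0),
            lengthscale=kwargs.get("lengthscale", 1.0),
        )
    if name == "sm":
        return SpectralMixtureKernel(
            weights=kwargs.get("weights", [1.0]),
            means=kwargs.get("means", [1.0]),
            scales=kwargs.get("scales", [0.5]),
        )
    raise ValueError(f"unknown kernel {name!r}; choose from {KERNEL_NAMES}")
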
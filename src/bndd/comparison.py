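"""Model comparison and Bayesian model averaging.

The evidence for a discontinuity is the Bayes factor

    BF10 = p(D | M1) / p(D | M0),

computed from the BIC-approximated log evidences.  The model posterior
combines the evidences with a prior over {M0, M1} (uniform by default).
Averaging the effect size over the two models yields a spike-and-slab
distribution: a point mass at d = 0 with weight p(M0 | D) and the
Gaussian (or curve) from M1 with weight p(M1 | D), which shrinks small
estimated effects towards zero.  When several candidate covariance
functions are entertained, their evidences are combined the same way
into a total Bayes factor and a kernel-marginal effect distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.special import logsumexp

from .models import EffectSize

__all__ = [
    "ComparisonResult",
    "bayes_factor",
    "model_posterior",
    "bma_effect",
    "kernel_bma",
]


def bayes_factor(log_ev1: float, log_ev0: float) -> float:
    """log BF10 = log p(D|M1) - log p(D|M0)."""
    if not (np.isfinite(log_ev1) and np.isfinite(log_ev0)):
        raise ValueError("log evidences must be finite")
    return float(log_ev1 - log_ev0)


def model_posterior(log_evidences: tuple[float, float],
                    priors: tuple[float, float] = (0.5, 0.5)) -> NDArray[np.float64]:
    """Posterior model probabilities (p(M0|D), p(M1|D)), computed in log space."""
    priors = np.asarray(priors, dtype=float)
    if priors.sum() <= 0 or np.any(priors < 0):
        raise ValueError("model priors must be nonnegative and sum to a positive value")
    if np.any(priors == 0) and np.all(priors == 0):
        raise ValueError("at least one model needs positive prior mass")
    log_ev = np.asarray(log_evidences, dtype=float)
    with np.errstate(divide="ignore"):
        log_post = log_ev + np.log(priors / priors.sum())
    log_post = log_post - logsumexp(log_post)
    return np.exp(log_post)


def bma_effect(effect: EffectSize, posterior, n_samples: int = 50_000,
               seed: int = 0) -> tuple[NDArray[np.float64], float]:
    """Draw from the spike-and-slab model average of the effect size.

    With probability p(M0|D) a draw is exactly 0; otherwise it comes from
    the Gaussian N(m, s^2) conditional on M1 (for its/geo the summary
    value and its variance are used).  Returns the samples and the exact
    point summary E[d | D] = p(M1|D) * m.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p0, p1 = float(posterior[0]), float(posterior[1])
    m = float(effect.m) if effect.mode == "rd" else float(effect.summary)
    s2 = float(effect.s2) if effect.mode == "rd" else float(effect.summary_s2)
    rng = np.random.default_rng(seed)
    spike = rng.random(n_samples) < p0
    samples = np.where(spike, 0.0, rng.normal(m, np.sqrt(s2), size=n_samples))
    return samples, p1 * m


@dataclass
class ComparisonResult:
    """Everything a discontinuity analysis reports."""

    mode: str
    log_evidence_m0: float
    log_evidence_m1: float
    log_bf10: float
    model_prior: tuple[float, float]
    model_posterior: NDArray[np.float64]
    effect_conditional: EffectSize
    bma_samples: NDArray[np.float64] = field(repr=False)
    bma_mean: float
    per_kernel: list[dict] = field(default_factory=list)
    log_bf_total: float = 0.0
    seed: int = 0

    @property
    def spike_mass(self) -> float:
        return float(np.mean(self.bma_samples == 0.0))


def kernel_bma(per_kernel: list[dict],
               kernel_prior: NDArray[np.float64] | None = None,
               effects: list[EffectSize] | None = None,
               model_prior: tuple[float, float] = (0.5, 0.5),
               n_samples: int = 50_000, seed: int = 0):
    """Combine evidences over a set of candidate covariance functions.

    ``per_kernel`` rows need ``log_ev_m0`` and ``log_ev_m1``.  The total
    Bayes factor is the ratio of kernel-prior-weighted summed evidences,
    computed with log-sum-exp.  If per-kernel effects are supplied, a
    kernel-marginal spike-and-slab sample is drawn by first picking a
    kernel with probability proportional to its evidence (under each
    model branch) and then sampling that kernel's model-averaged effect.

    Returns ``(log_bf_total, samples)``; ``samples`` is None when no
    effects are given.
    """
    if len(per_kernel) == 0:
        raise ValueError("kernel set is empty")
    K = len(per_kernel)
    if kernel_prior is None:
        kernel_prior = np.full(K, 1.0 / K)
    kernel_prior = np.asarray(kernel_prior, dtype=float)
    if kernel_prior.size != K or np.any(kernel_prior < 0) or kernel_prior.sum() <= 0:
        raise ValueError("kernel prior must be a nonnegative vector over the kernel set")
    kernel_prior = kernel_prior / kernel_prior.sum()

    lev0 = np.array([row["log_ev_m0"] for row in per_kernel], dtype=float)
    lev1 = np.array([row["log_ev_m1"] for row in per_kernel], dtype=float)
    with np.errstate(divide="ignore"):
        lp = np.log(kernel_prior)
    log_num = logsumexp(lev1 + lp)
    log_den = logsumexp(lev0 + lp)
    log_bf_total = float(log_num - log_den)

    if effects is None:
        return log_bf_total, None

    if len(effects) != K:
        raise ValueError("need one effect per kernel")
    rng = np.random.default_rng(seed)
    # joint posterior over (model, kernel)
    pri = np.asarray(model_prior, dtype=float)
    pri = pri / pri.sum()
    with np.errstate(divide="ignore"):
        lj0 = lev0 + lp + np.log(pri[0])
        lj1 = lev1 + lp + np.log(pri[1])
    lj = np.concatenate([lj0, lj1])
    pj = np.exp(lj - logsumexp(lj))
    choice = rng.choice(2 * K, size=n_samples, p=pj)
    samples = np.zeros(n_samples)
    slab = choice >= K
    for k in range(K):
        pick = slab & (choice == K + k)
        if not pick.any():
            continue
        e = effects[k]
        m = float(e.m) if e.mode == "rd" else float(e.summary)
        s2 = float(e.s2) if e.mode == "rd" else float(e.summary_s2)
        samples[pick] = rng.normal(m, np.sqrt(s2), size=int(pick.sum()))
    return log_bf_total, samples
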
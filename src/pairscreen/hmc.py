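"""A compact Hamiltonian Monte Carlo sampler.

Static-path HMC with leapfrog integration, dual-averaging step-size
adaptation toward a target acceptance rate, and diagonal mass-matrix
estimation during warmup. The target density must supply an analytic
gradient; chains are run independently so between/within-chain diagnostics
(R-hat) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_hmc", "HMCResult"]


@dataclass
class HMCResult:
    samples: np.ndarray  # (n_chains, n_kept, dim), post-warmup draws
    accept_rate: np.ndarray  # (n_chains,)
    step_sizes: np.ndarray  # (n_chains,) adapted step sizes


def _leapfrog(z, p, grad, eps, n_steps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        z = z + eps * inv_mass * p
        lp, grad = logp_grad(z)
        if i < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return z, p, lp, grad


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    n_samples: int,
    n_warmup: int,
    rng: np.random.Generator,
    n_leapfrog: int = 20,
    target_accept: float = 0.8,
    init_step: float = 0.1,
) -> tuple[np.ndarray, float, float]:
    """Run one HMC chain; returns (kept draws, acceptance rate, final step size).

    ``n_samples`` counts total iterations including the ``n_warmup`` draws
    that are discarded. Step size follows Nesterov dual averaging during
    warmup; a diagonal mass matrix is estimated from the second half of
    warmup and applied thereafter.
    """
    dim = init.size
    z = init.astype(float).copy()
    lp, grad = logp_grad(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = init_step
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    inv_mass = np.ones(dim)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    kept = np.empty((n_samples - n_warmup, dim))
    n_accept = 0
    for it in range(n_samples):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        steps = int(rng.integers(max(1, n_leapfrog // 2), n_leapfrog + 1))
        z_new, p_new, lp_new, grad_new = _leapfrog(z, p, grad, eps, steps, inv_mass, logp_grad)
        h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
        log_alpha = min(0.0, h1 - h0) if np.isfinite(h1) else -np.inf
        accept_prob = np.exp(log_alpha)
        if np.log(rng.random()) < log_alpha:
            z, lp, grad = z_new, lp_new, grad_new
            if it >= n_warmup:
                n_accept += 1
        if it < n_warmup:
            # dual averaging on log step size
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if it >= n_warmup // 2:
                welford_n += 1
                delta = z - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (z - welford_mean)
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
                if welford_n > 10:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = np.clip(var, 1e-4, 1e4)
        else:
            kept[it - n_warmup] = z
    n_kept = n_samples - n_warmup
    return kept, n_accept / max(1, n_kept), eps
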
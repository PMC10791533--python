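"""A small Hamiltonian Monte Carlo sampler with dual-averaging adaptation.

Static-trajectory HMC with a jittered number of leapfrog steps, dual
averaging of the step size toward a target acceptance rate (Hoffman &
Gelman 2014, Algorithm 5) and a diagonal mass matrix estimated from a
warmup window.  Deterministic given the supplied Generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

#: Energy error above which a trajectory is treated as divergent.
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    samples: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float
    inv_mass: np.ndarray


class _DualAveraging:
    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.t = 0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_grad, theta, rho, eps, n_steps, inv_mass):
    lp, grad = logp_grad(theta)
    rho = rho + 0.5 * eps * grad
    for i in range(n_steps):
        theta = theta + eps * inv_mass * rho
        lp, grad = logp_grad(theta)
        if not np.isfinite(lp):
            return theta, rho, -np.inf
        rho = rho + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return theta, rho, lp


def _find_initial_step(logp_grad, theta, inv_mass, rng, eps=0.1):
    """Double/halve eps until the one-step acceptance probability crosses 0.5."""
    lp0, _ = logp_grad(theta)
    rho = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)

    def accept_logprob(e):
        th, rh, lp = _leapfrog(logp_grad, theta, rho.copy(), e, 1, inv_mass)
        if not np.isfinite(lp):
            return -np.inf
        return (lp - 0.5 * np.sum(rh**2 * inv_mass)) - (
            lp0 - 0.5 * np.sum(rho**2 * inv_mass)
        )

    a = 1.0 if accept_logprob(eps) > np.log(0.5) else -1.0
    for _ in range(50):
        if a * accept_logprob(eps) <= -a * np.log(2.0):
            break
        eps *= 2.0**a
    return float(np.clip(eps, 1e-8, 1e3))


def sample_chain(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    n_leapfrog: int = 24,
    jitter: float = 0.3,
) -> ChainResult:
    """Run one HMC chain: ``n_warmup`` adaptation iterations then ``n_draws``.

    Warmup schedule: step-size adaptation throughout; posterior variances
    accumulated over the middle window [0.25, 0.85) of warmup define the
    diagonal inverse mass matrix, after which the step size is re-adapted.
    """
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    w_lo, w_hi = int(0.25 * n_warmup), int(0.85 * n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    samples = np.empty((n_draws, dim))
    n_accept = 0
    divergences = 0
    lp_cur, _ = logp_grad(theta)

    for it in range(n_warmup + n_draws):
        rho0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        steps = max(1, int(round(n_leapfrog * rng.uniform(1 - jitter, 1 + jitter))))
        theta_new, rho_new, lp_new = _leapfrog(
            logp_grad, theta, rho0.copy(), eps, steps, inv_mass
        )
        h0 = -lp_cur + 0.5 * np.sum(rho0**2 * inv_mass)
        h1 = -lp_new + 0.5 * np.sum(rho_new**2 * inv_mass) if np.isfinite(lp_new) else np.inf
        delta_h = h1 - h0
        if not np.isfinite(delta_h) or delta_h > DIVERGENCE_THRESHOLD:
            accept_prob = 0.0
            if it >= n_warmup:
                divergences += 1
        else:
            accept_prob = min(1.0, float(np.exp(-delta_h)))
        if rng.uniform() < accept_prob:
            theta = theta_new
            lp_cur = lp_new
        if it < n_warmup:
            eps = da.update(accept_prob)
            if w_lo <= it < w_hi:
                welford_n += 1
                d = theta - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (theta - welford_mean)
            if it == w_hi - 1 and welford_n > 10:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit scale as Stan does
                inv_mass = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                    5.0 / (welford_n + 5.0)
                )
                eps = _find_initial_step(logp_grad, theta, inv_mass, rng, eps)
                da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            samples[it - n_warmup] = theta
            n_accept += accept_prob
    return ChainResult(
        samples=samples,
        accept_rate=n_accept / n_draws,
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
    )
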
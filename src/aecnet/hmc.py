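"""Adaptive Hamiltonian Monte Carlo.

A compact gradient-based MCMC engine for the hierarchical model: leapfrog
integration with a jittered trajectory length, dual-averaging step-size
adaptation toward a target acceptance rate, and diagonal mass-matrix
(inverse metric) estimation from the second half of warmup. Divergent
transitions (energy error > 1000) are rejected and counted.

The target density is supplied as a callable returning the log posterior
and its gradient on the unconstrained scale; any constrained parameters
must be transformed (with Jacobians) by the caller.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    """Post-warmup draws and sampler health counters for one run."""

    draws: np.ndarray  # (chains, n_draws, dim)
    accept_rate: np.ndarray  # per chain
    divergences: np.ndarray  # per chain
    step_size: np.ndarray  # per chain, post-adaptation


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp) or not np.isfinite(grad).all():
            return x, p, -np.inf, grad, False
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return x, p, logp, grad, True


def _sample_one_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float,
    trajectory_length: float,
    max_leapfrog: int,
    init_step: float,
) -> tuple[np.ndarray, float, int, float]:
    dim = x0.size
    x = x0.copy()
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    eps = init_step

    class _DualAveraging:
        """Nesterov dual averaging toward the target acceptance rate."""

        gamma, t0, kappa = 0.05, 10.0, 0.75

        def __init__(self, eps0: float):
            self.mu = np.log(10 * eps0)
            self.log_eps_bar = np.log(eps0)
            self.h_bar = 0.0
            self.m = 0

        def update(self, accept_prob: float) -> float:
            self.m += 1
            frac = 1.0 / (self.m + self.t0)
            self.h_bar = (1 - frac) * self.h_bar + frac * (target_accept - accept_prob)
            log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
            w = self.m ** (-self.kappa)
            self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
            return float(np.exp(log_eps))

    adapt = _DualAveraging(eps)
    window = []  # draws used to estimate the diagonal metric
    # two expanding adaptation windows; step size re-adapts after each
    mass_updates = [max(1, int(f * n_warmup)) for f in (0.45, 0.85)]
    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0
    total = n_warmup + n_draws

    for it in range(total):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float(p * inv_mass @ p)
        jitter = rng.uniform(0.8, 1.0)
        n_steps = int(np.clip(round(trajectory_length * jitter / eps), 1, max_leapfrog))
        x_new, p_new, logp_new, grad_new, ok = _leapfrog(
            logp_grad, x, p, grad, eps, n_steps, inv_mass
        )
        if ok:
            with np.errstate(over="ignore", invalid="ignore"):
                h1 = logp_new - 0.5 * float(p_new * inv_mass @ p_new)
            delta = h1 - h0 if np.isfinite(h1) else -np.inf
            accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
            if delta < -1000.0:
                accept_prob = 0.0
                if it >= n_warmup:
                    n_div += 1
        else:
            accept_prob = 0.0
            if it >= n_warmup:
                n_div += 1
        if rng.uniform() < accept_prob:
            x, logp, grad = x_new, logp_new, grad_new
            if it >= n_warmup:
                n_accept += 1

        if it < n_warmup:
            eps = adapt.update(accept_prob)
            if it >= n_warmup // 5:
                window.append(x.copy())
            if it in mass_updates and len(window) > 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = np.clip(var, 1e-8, None)
                window = []
                # restart step-size adaptation under the new metric
                adapt = _DualAveraging(eps)
            if it == n_warmup - 1:
                eps = float(np.exp(adapt.log_eps_bar))
        else:
            draws[it - n_warmup] = x

    return draws, n_accept / max(n_draws, 1), n_div, eps


def sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 1500,
    seed: int = 0,
    target_accept: float = 0.85,
    trajectory_length: float = 3.0,
    max_leapfrog: int = 64,
    init_step: float = 0.1,
    init_jitter: float = 0.5,
) -> HMCResult:
    """Run independent adaptive HMC chains.

    Chains start from ``x0`` plus Gaussian jitter and use independent
    seed-sequence substreams, so results are reproducible given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    chain_draws, rates, divs, steps = [], [], [], []
    for child in ss.spawn(n_chains):
        rng = np.random.default_rng(child)
        start = x0 + init_jitter * rng.standard_normal(x0.size)
        d, r, nd, e = _sample_one_chain(
            logp_grad, start, n_warmup, n_draws, rng,
            target_accept, trajectory_length, max_leapfrog, init_step,
        )
        chain_draws.append(d)
        rates.append(r)
        divs.append(nd)
        steps.append(e)
    return HMCResult(
        draws=np.asarray(chain_draws),
        accept_rate=np.asarray(rates),
        divergences=np.asarray(divs),
        step_size=np.asarray(steps),
    )
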
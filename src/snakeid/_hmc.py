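"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

Jittered-trajectory HMC with dual-averaging step-size adaptation (target
acceptance 0.8) and diagonal mass-matrix estimation during warmup.  The
target is supplied as a single callable returning the log density and its
gradient; all model-specific structure (transforms, Jacobians, priors) lives
with the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim)
    accept_rate: float
    step_size: float
    n_divergent: int
    logp: np.ndarray           # (n_draws,)


def _leapfrog(logp_grad: LogpGrad, q, p, grad, step, n_steps, inv_mass):
    """Standard leapfrog integrator; returns final state and gradient."""
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        q = q + step * inv_mass * p
        lp, grad = logp_grad(q)
        if i < n_steps - 1:
            p = p + step * grad
    p = p + 0.5 * step * grad
    return q, p, lp, grad


def _find_initial_step(logp_grad, q, inv_mass, rng):
    """Heuristic: double/halve until the one-step acceptance crosses 0.5."""
    step = 0.1
    lp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p * p)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, step, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        step *= 2.0 ** direction
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, step, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return step


def sample_chain(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
) -> ChainResult:
    """Run one HMC chain and return post-warmup draws.

    The trajectory length is jittered (uniform 1..max_leapfrog steps) which
    avoids the resonance pathologies of fixed-length HMC.  The diagonal mass
    matrix is re-estimated from warmup draws at 50% and 90% of warmup, with
    dual averaging restarted after each update.
    """
    with np.errstate(over="ignore", invalid="ignore", under="ignore",
                     divide="ignore"):
        return _sample_chain(logp_grad, q0, n_warmup, n_draws, rng,
                             max_leapfrog, target_accept)


def _sample_chain(logp_grad, q0, n_warmup, n_draws, rng,
                  max_leapfrog, target_accept) -> ChainResult:
    dim = q0.size
    q = q0.astype(float).copy()
    inv_mass = np.ones(dim)

    step = _find_initial_step(logp_grad, q, inv_mass, rng)
    mu = np.log(10.0 * step)
    log_step_bar, h_bar = np.log(step), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    mass_updates = sorted({int(0.5 * n_warmup), int(0.9 * n_warmup)})
    window: list[np.ndarray] = []

    lp, grad = logp_grad(q)
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    n_accept = 0
    n_div = 0
    total = n_warmup + n_draws

    for it in range(total):
        warming = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        q_new, p_new, lp_new, grad_new = _leapfrog(
            logp_grad, q, p, grad, step, n_steps, inv_mass
        )
        h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
        delta = h1 - h0
        if not np.isfinite(delta):
            delta = -np.inf
        if delta < -1000 and not warming:
            n_div += 1
        accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
        if rng.random() < accept_prob:
            q, lp, grad = q_new, lp_new, grad_new
            if not warming:
                n_accept += 1

        if warming:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_step = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))

            window.append(q.copy())
            if it + 1 in mass_updates and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                n_w = len(window)
                # regularized like Stan's diagonal metric adaptation;
                # inverse mass = posterior variance estimate
                inv_mass = n_w / (n_w + 5.0) * var + 1e-3 * (5.0 / (n_w + 5.0))
                window.clear()
                step = _find_initial_step(logp_grad, q, inv_mass, rng)
                mu = np.log(10.0 * step)
                log_step_bar, h_bar, adapt_iter = np.log(step), 0.0, 0
        else:
            if it == n_warmup:
                step = float(np.exp(log_step_bar))
            i = it - n_warmup
            draws[i] = q
            logps[i] = lp

    return ChainResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=step,
        n_divergent=n_div,
        logp=logps,
    )
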
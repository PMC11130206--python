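"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter space.

The models in this package expose a differentiable log posterior density on
an unconstrained vector (positive parameters are log-transformed with the
Jacobian folded into the density, correlations tanh-transformed).  This
module provides the sampler that all of them share: Hamiltonian Monte Carlo
with

* dual-averaging step-size adaptation toward a target acceptance rate
  (Hoffman & Gelman's scheme),
* a diagonal mass matrix estimated from the second half of a first warmup
  window, after which the step size is re-adapted,
* a uniformly jittered number of leapfrog steps per iteration, which
  decorrelates successive draws without a full dynamic trajectory length.

Chains are seeded independently from ``(seed, chain)`` via NumPy's
``SeedSequence`` spawning, so runs are bit-reproducible for a fixed seed and
NumPy version.  A proposal whose energy error exceeds a large cutoff is
counted as a divergence and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

__all__ = ["LogDensityModel", "hmc_sample"]

_ENERGY_DIVERGENCE = 500.0


class LogDensityModel(Protocol):
    """Differentiable target density on an unconstrained space."""

    #: names of the reported (constrained-scale) parameters
    names: list[str]
    #: dimension of the unconstrained space
    dim: int

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]: ...

    def initial_position(self, rng: np.random.Generator) -> np.ndarray: ...

    def transform(self, theta: np.ndarray) -> np.ndarray:
        """Map an unconstrained position to the reported parameter vector."""
        ...


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""

    mu: float
    delta: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self._t += 1
        frac = 1.0 / (self._t + self.t0)
        self._h_bar = (1 - frac) * self._h_bar + frac * (self.delta - accept_prob)
        log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** (-self.kappa)
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


def _find_initial_step(
    logp_and_grad: Callable, theta: np.ndarray, inv_mass: np.ndarray, rng: np.random.Generator
) -> float:
    """Heuristic doubling/halving until the one-step accept prob crosses 1/2."""
    eps = 0.1
    lp0, grad0 = logp_and_grad(theta)
    p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = -lp0 + 0.5 * np.sum(p0**2 * inv_mass)

    def one_step(eps: float) -> float:
        p = p0 + 0.5 * eps * grad0
        q = theta + eps * inv_mass * p
        lp, grad = logp_and_grad(q)
        p = p + 0.5 * eps * grad
        h = -lp + 0.5 * np.sum(p**2 * inv_mass)
        return h0 - h  # log accept ratio

    ratio = one_step(eps)
    if not np.isfinite(ratio):
        ratio = -np.inf
    direction = 1.0 if ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        ratio = one_step(eps)
        if not np.isfinite(ratio):
            ratio = -np.inf
        if direction * ratio <= direction * np.log(0.5):
            break
    return eps


def _leapfrog(
    logp_and_grad: Callable,
    theta: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        lp, grad = logp_and_grad(theta)
        if not np.isfinite(lp):
            return theta, p, lp, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def hmc_sample(
    model: LogDensityModel,
    n_chains: int,
    n_iterations: int,
    n_warmup: int,
    seed: int,
    target_accept: float = 0.8,
    max_leapfrog: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Run HMC chains; return (draws, divergences).

    ``draws`` has shape ``(n_chains, n_iterations - n_warmup, len(model.names))``
    on the reported (constrained) scale; ``divergences`` counts post-warmup
    divergent proposals per chain.
    """
    if n_warmup >= n_iterations:
        raise ValueError("n_warmup must be < n_iterations")
    n_keep = n_iterations - n_warmup
    n_report = len(model.names)
    draws = np.empty((n_chains, n_keep, n_report))
    divergences = np.zeros(n_chains, dtype=np.int64)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)

    for chain in range(n_chains):
        rng = np.random.default_rng(seeds[chain])
        theta = np.asarray(model.initial_position(rng), dtype=float)
        dim = theta.size
        inv_mass = np.ones(dim)
        lp, grad = model.logp_and_grad(theta)
        if not np.isfinite(lp):
            raise RuntimeError("non-finite log density at the initial position")

        eps = _find_initial_step(model.logp_and_grad, theta, inv_mass, rng)
        da = _DualAveraging(mu=np.log(10.0 * eps), delta=target_accept)
        phase1_end = max(n_warmup // 2, 1)
        window: list[np.ndarray] = []

        for it in range(n_iterations):
            p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            h0 = -lp + 0.5 * np.sum(p0**2 * inv_mass)
            theta_new, p_new, lp_new, grad_new = _leapfrog(
                model.logp_and_grad, theta, p0, grad, eps, n_steps, inv_mass
            )
            if np.isfinite(lp_new):
                h_new = -lp_new + 0.5 * np.sum(p_new**2 * inv_mass)
                delta_h = h0 - h_new
            else:
                delta_h = -np.inf
            divergent = (not np.isfinite(delta_h)) or (-delta_h > _ENERGY_DIVERGENCE)
            accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))
            if (not divergent) and np.log(rng.random()) < delta_h:
                theta, lp, grad = theta_new, lp_new, grad_new

            if it < n_warmup:
                eps = da.update(accept_prob)
                if it >= phase1_end // 2 and it < phase1_end:
                    window.append(theta.copy())
                if it == phase1_end - 1 and len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0, ddof=1)
                    inv_mass = np.clip(var, 1e-8, None)
                    eps = _find_initial_step(model.logp_and_grad, theta, inv_mass, rng)
                    da = _DualAveraging(mu=np.log(10.0 * eps), delta=target_accept)
                if it == n_warmup - 1:
                    eps = da.adapted
            else:
                if divergent:
                    divergences[chain] += 1
                draws[chain, it - n_warmup] = model.transform(theta)

    return draws, divergences
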
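"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A compact, dependency-free implementation of dynamic Hamiltonian Monte Carlo
for a differentiable unnormalised log density.  The warmup schedule is a
simplified Stan-style scheme: the first half of warmup adapts only the step
size against a unit metric, a diagonal metric is then estimated from the
collected draws, and step-size adaptation restarts against the new metric for
the second half.  Trees are built by the slice-sampling NUTS recursion with a
configurable maximum depth; proposals whose energy error exceeds
``DIVERGENCE_THRESHOLD`` are counted as divergent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    samples: np.ndarray  # (n_samples, dim)
    logp: np.ndarray  # (n_samples,)
    divergences: int = 0
    step_size: float = 0.0
    mean_accept: float = 0.0
    mean_tree_depth: float = 0.0
    inv_mass: np.ndarray = field(default_factory=lambda: np.empty(0))


class _Target:
    """Caches the (logp, grad) pair of the most recent point."""

    def __init__(self, logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]]):
        self.f = logp_grad
        self.n_evals = 0

    def __call__(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_evals += 1
        lp, g = self.f(q)
        if not np.isfinite(lp):
            lp = -np.inf
            g = np.zeros_like(q)
        return lp, g


def _leapfrog(target, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    lp, grad = target(q)
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _kinetic(p, inv_mass) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def _find_reasonable_epsilon(target, q0, lp0, grad0, inv_mass, rng) -> float:
    eps = 0.1
    p0 = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    h0 = lp0 - _kinetic(p0, inv_mass)
    _, p1, lp1, _ = _leapfrog(target, q0, p0, grad0, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass)
    d = h1 - h0
    direction = 1.0 if d > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(target, q0, p0, grad0, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return eps


def _build_tree(target, q, p, grad, log_u, direction, depth, eps, h0, inv_mass, rng):
    """Recursive doubling; returns (q, p, grad, q_other_end...) via tree state."""
    if depth == 0:
        q1, p1, lp1, grad1 = _leapfrog(target, q, p, grad, direction * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = 1 if log_u <= h1 else 0
        divergent = log_u - DIVERGENCE_THRESHOLD > h1
        alpha = min(1.0, math.exp(min(0.0, h1 - h0)))
        return q1, p1, grad1, lp1, q1, p1, grad1, q1, lp1, grad1, n1, (not divergent), alpha, 1, divergent
    # first half
    (qm, pm, gm, lpm, qp, pp, gp, qprop, lpprop, gprop,
     n1, ok1, a1, na1, div1) = _build_tree(
        target, q, p, grad, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
    if ok1:
        if direction == -1:
            (qm, pm, gm, _lp, _qp, _pp, _gp, qprop2, lpprop2, gprop2,
             n2, ok2, a2, na2, div2) = _build_tree(
                target, qm, pm, gm, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
        else:
            (_qm, _pm, _gm, _lp, qp, pp, gp, qprop2, lpprop2, gprop2,
             n2, ok2, a2, na2, div2) = _build_tree(
                target, qp, pp, gp, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            qprop, lpprop, gprop = qprop2, lpprop2, gprop2
        dq = qp - qm
        ok1 = (
            ok2
            and float(np.dot(dq, inv_mass * pm)) >= 0.0
            and float(np.dot(dq, inv_mass * pp)) >= 0.0
        )
        n1 += n2
        a1 += a2
        na1 += na2
        div1 = div1 or div2
    return qm, pm, gm, lpm, qp, pp, gp, qprop, lpprop, gprop, n1, ok1, a1, na1, div1


def _nuts_step(target, q, lp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p0, inv_mass)
    log_u = h0 + math.log(max(rng.random(), 1e-300))
    qm = qp = q
    pm = pp = p0
    gm = gp = grad
    q_new, lp_new, grad_new = q, lp, grad
    n = 1
    depth = 0
    sum_alpha, n_alpha = 0.0, 0
    divergent = False
    keep_going = True
    while keep_going and depth < max_depth:
        direction = -1 if rng.random() < 0.5 else 1
        if direction == -1:
            (qm, pm, gm, _lp, _qp, _pp, _gp, qprop, lpprop, gprop,
             n1, ok, a, na, div) = _build_tree(
                target, qm, pm, gm, log_u, direction, depth, eps, h0, inv_mass, rng)
        else:
            (_qm, _pm, _gm, _lp, qp, pp, gp, qprop, lpprop, gprop,
             n1, ok, a, na, div) = _build_tree(
                target, qp, pp, gp, log_u, direction, depth, eps, h0, inv_mass, rng)
        sum_alpha += a
        n_alpha += na
        divergent = divergent or div
        if ok and n1 > 0 and rng.random() < min(1.0, n1 / n):
            q_new, lp_new, grad_new = qprop, lpprop, gprop
        n += n1
        dq = qp - qm
        keep_going = (
            ok
            and float(np.dot(dq, inv_mass * pm)) >= 0.0
            and float(np.dot(dq, inv_mass * pp)) >= 0.0
        )
        depth += 1
    accept_stat = sum_alpha / max(n_alpha, 1)
    return q_new, lp_new, grad_new, accept_stat, depth, divergent


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept rate."""

    def __init__(self, eps0: float, target: float = 0.8):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    max_depth: int = 8,
    target_accept: float = 0.8,
) -> NutsResult:
    """Draw ``n_samples`` from a log density after ``n_warmup`` adaptation steps."""
    target = _Target(logp_grad)
    q = np.array(q0, dtype=float)
    lp, grad = target(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log probability")
    dim = q.size
    inv_mass = np.ones(dim)

    # metric re-estimation points: two expanding windows, Stan-style, each
    # using only the draws generated under the previous metric
    updates = []
    if n_warmup >= 80:
        updates = [int(0.3 * n_warmup), int(0.6 * n_warmup)]
    warm_draws = np.empty((n_warmup, dim))
    eps = _find_reasonable_epsilon(target, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    window_start = 0
    for i in range(n_warmup):
        if i in updates:
            tail = warm_draws[window_start + (i - window_start) // 3 : i]
            var = np.var(tail, axis=0)
            nw = tail.shape[0]
            inv_mass = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
            inv_mass = np.maximum(inv_mass, 1e-10)
            eps = _find_reasonable_epsilon(target, q, lp, grad, inv_mass, rng)
            da = _DualAveraging(eps, target_accept)
            window_start = i
        q, lp, grad, alpha, _, _ = _nuts_step(
            target, q, lp, grad, eps, inv_mass, max_depth, rng
        )
        eps = da.update(alpha)
        warm_draws[i] = q
    eps = da.adapted

    samples = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    divergences = 0
    acc_sum = 0.0
    depth_sum = 0
    for i in range(n_samples):
        q, lp, grad, alpha, depth, div = _nuts_step(
            target, q, lp, grad, eps, inv_mass, max_depth, rng
        )
        samples[i] = q
        logps[i] = lp
        divergences += int(div)
        acc_sum += alpha
        depth_sum += depth
    return NutsResult(
        samples=samples,
        logp=logps,
        divergences=divergences,
        step_size=eps,
        mean_accept=acc_sum / max(n_samples, 1),
        mean_tree_depth=depth_sum / max(n_samples, 1),
        inv_mass=inv_mass,
    )
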
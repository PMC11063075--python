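"""Gradient-based MCMC: No-U-Turn sampling with adaptation and diagnostics.

A self-contained implementation of the No-U-Turn Sampler (dynamic
Hamiltonian Monte Carlo) over a user-supplied log-posterior and gradient
on an unconstrained parameter vector.  Warmup adapts the step size by
dual averaging toward a target acceptance statistic and the diagonal mass
matrix from warmup draws in expanding windows.  Divergent transitions
(energy error beyond a fixed threshold) are counted and reported.

Convergence diagnostics (split-R-hat, bulk and tail effective sample
size) are computed with arviz over named, constrained-space draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

import logging

logging.getLogger("arviz").setLevel(logging.ERROR)

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent transition

# diagnostics contract for a fit to count as passed
RHAT_MAX = 1.01
ESS_MIN = 500.0
DIVERGENCE_RATE_MAX = 0.0005


@dataclass
class RawChains:
    positions: np.ndarray  # chains x draws x ndim (unconstrained)
    divergences: np.ndarray  # chains x draws bool
    accept_stat: np.ndarray  # chains x draws
    step_size: np.ndarray  # per chain
    tree_depth: np.ndarray  # chains x draws


@dataclass
class PosteriorDraws:
    """Named constrained-space draws with MCMC diagnostics.

    ``draws`` maps parameter names to arrays of shape (chains, iterations,
    *param_shape).  ``passed`` reflects the diagnostics contract: split
    R-hat < 1.01 and bulk/tail ESS > 500 for every parameter, with fewer
    than 0.05% of iterations ending in a divergence.
    """

    draws: dict[str, np.ndarray]
    diagnostics: pd.DataFrame
    n_divergent: int
    n_iterations: int
    passed: bool
    notes: dict = field(default_factory=dict)

    @property
    def divergence_rate(self) -> float:
        return self.n_divergent / max(self.n_iterations, 1)

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter flattened over chains: (total_draws, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])


# ---------------------------------------------------------------------------
# leapfrog + NUTS tree
# ---------------------------------------------------------------------------

def _leapfrog(q, p, grad, eps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    lp, g = logp_grad(q)
    p = p + 0.5 * eps * g
    return q, p, lp, g


class _Tree:
    """Recursive NUTS trajectory builder (slice-sampling variant)."""

    def __init__(self, logp_grad: LogpGrad, eps: float, inv_mass: np.ndarray,
                 log_u: float, joint0: float, rng: np.random.Generator):
        self.logp_grad = logp_grad
        self.eps = eps
        self.inv_mass = inv_mass
        self.log_u = log_u
        self.joint0 = joint0
        self.rng = rng
        self.divergent = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def _joint(self, lp: float, p: np.ndarray) -> float:
        return lp - 0.5 * float(np.sum(self.inv_mass * p * p))

    def build(self, q, p, grad, direction, depth):
        if depth == 0:
            q1, p1, lp1, g1 = _leapfrog(
                q, p, grad, direction * self.eps, self.inv_mass, self.logp_grad
            )
            joint = self._joint(lp1, p1) if np.isfinite(lp1) else -np.inf
            n_valid = int(self.log_u <= joint)
            keep_going = self.log_u < joint + DIVERGENCE_THRESHOLD
            if not keep_going:
                self.divergent = True
            self.alpha_sum += min(1.0, float(np.exp(min(joint - self.joint0, 0.0))))
            self.n_alpha += 1
            return q1, p1, g1, q1, p1, g1, q1, lp1, n_valid, keep_going
        # build left and right subtrees
        qm, pm, gm, qp, pp, gp, qprop, lpprop, n1, s1 = self.build(
            q, p, grad, direction, depth - 1
        )
        if s1:
            if direction == -1:
                qm, pm, gm, _, _, _, qprop2, lpprop2, n2, s2 = self.build(
                    qm, pm, gm, direction, depth - 1
                )
            else:
                _, _, _, qp, pp, gp, qprop2, lpprop2, n2, s2 = self.build(
                    qp, pp, gp, direction, depth - 1
                )
            if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                qprop, lpprop = qprop2, lpprop2
            dq = qp - qm
            s1 = (
                s2
                and float(np.dot(dq, self.inv_mass * pm)) >= 0
                and float(np.dot(dq, self.inv_mass * pp)) >= 0
            )
            n1 += n2
        return qm, pm, gm, qp, pp, gp, qprop, lpprop, n1, s1


def _nuts_step(logp_grad, q, lp, grad, eps, inv_mass, max_depth, rng):
    mass = 1.0 / inv_mass
    p0 = rng.standard_normal(q.size) * np.sqrt(mass)
    joint0 = lp - 0.5 * float(np.sum(inv_mass * p0 * p0))
    log_u = joint0 + np.log(rng.random())
    tree = _Tree(logp_grad, eps, inv_mass, log_u, joint0, rng)
    qm = qp = q
    pm = pp = p0
    gm = gp = grad
    q_new, lp_new = q, lp
    grad_new = grad
    n = 1
    depth = 0
    s = True
    while s and depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            qm, pm, gm, _, _, _, qprop, lpprop, n1, s1 = tree.build(
                qm, pm, gm, direction, depth
            )
        else:
            _, _, _, qp, pp, gp, qprop, lpprop, n1, s1 = tree.build(
                qp, pp, gp, direction, depth
            )
        if s1 and n1 > 0 and rng.random() < min(1.0, n1 / n):
            q_new, lp_new = qprop, lpprop
        n += n1
        dq = qp - qm
        s = (
            s1
            and float(np.dot(dq, inv_mass * pm)) >= 0
            and float(np.dot(dq, inv_mass * pp)) >= 0
        )
        depth += 1
    if not np.array_equal(q_new, q):
        _, grad_new = logp_grad(q_new)
    accept_stat = tree.alpha_sum / max(tree.n_alpha, 1)
    return q_new, lp_new, grad_new, accept_stat, tree.divergent, depth


def _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng):
    eps = 1.0
    mass = 1.0 / inv_mass
    p = rng.standard_normal(q.size) * np.sqrt(mass)
    joint0 = lp - 0.5 * float(np.sum(inv_mass * p * p))
    _, p1, lp1, _ = _leapfrog(q, p, grad, eps, inv_mass, logp_grad)
    joint1 = lp1 - 0.5 * float(np.sum(inv_mass * p1 * p1)) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(100):
        eps = eps * (2.0**direction)
        _, p1, lp1, _ = _leapfrog(q, p, grad, eps, inv_mass, logp_grad)
        joint1 = (
            lp1 - 0.5 * float(np.sum(inv_mass * p1 * p1)) if np.isfinite(lp1) else -np.inf
        )
        if direction * (joint1 - joint0) < direction * np.log(0.5):
            break
    return eps


def sample_nuts(
    logp_grad: LogpGrad,
    ndim: int,
    chains: int = 4,
    warmup: int = 1000,
    samples: int = 1000,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
    seed: int = 0,
    init: np.ndarray | None = None,
    init_scale: float = 0.1,
) -> RawChains:
    """Run NUTS chains over an unconstrained log posterior.

    Warmup uses dual averaging (Stan's gamma=0.05, t0=10, kappa=0.75)
    toward ``target_accept``, with the diagonal mass matrix re-estimated
    from draw variances at 50% and 80% of warmup (step size re-adapted
    after each update).  Post-warmup draws use the averaged step size.
    """
    user_logp_grad = logp_grad

    def logp_grad(q):  # noqa: F811 - guarded wrapper
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, g = user_logp_grad(q)
        if not np.isfinite(lp) or not np.all(np.isfinite(g)):
            return -np.inf, np.zeros_like(q)
        return lp, g

    positions = np.empty((chains, samples, ndim))
    divergences = np.zeros((chains, samples), dtype=bool)
    accept = np.zeros((chains, samples))
    depths = np.zeros((chains, samples), dtype=int)
    step_sizes = np.zeros(chains)

    windows = sorted({int(warmup * 0.5), int(warmup * 0.8)})
    errstate = np.errstate(over="ignore", invalid="ignore", divide="ignore")
    errstate.__enter__()
    for c in range(chains):
        rng = np.random.default_rng([int(seed), c])
        q = (
            init.copy()
            if init is not None
            else rng.normal(0.0, init_scale, size=ndim)
        )
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log posterior")
        inv_mass = np.ones(ndim)
        eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng)
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        adapt_iter = 0
        buffer: list[np.ndarray] = []
        for it in range(warmup):
            q, lp, grad, a_stat, _, _ = _nuts_step(
                logp_grad, q, lp, grad, eps, inv_mass, max_treedepth, rng
            )
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - a_stat)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            buffer.append(q.copy())
            if (it + 1) in windows and len(buffer) > 10:
                var = np.var(np.asarray(buffer), axis=0)
                inv_mass = np.clip(var, 1e-8, None)
                buffer = []
                eps = _find_initial_step(logp_grad, q, lp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
        eps = float(np.exp(log_eps_bar)) if warmup > 0 else eps
        step_sizes[c] = eps
        for it in range(samples):
            q, lp, grad, a_stat, div, depth = _nuts_step(
                logp_grad, q, lp, grad, eps, inv_mass, max_treedepth, rng
            )
            positions[c, it] = q
            divergences[c, it] = div
            accept[c, it] = a_stat
            depths[c, it] = depth
    errstate.__exit__(None, None, None)
    return RawChains(
        positions=positions,
        divergences=divergences,
        accept_stat=accept,
        step_size=step_sizes,
        tree_depth=depths,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def diagnose(draws: dict[str, np.ndarray], divergences: np.ndarray) -> tuple[pd.DataFrame, bool]:
    """Split-R-hat and bulk/tail ESS per parameter; overall pass verdict."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=draws)
        rhat = az.rhat(idata)
        ess_bulk = az.ess(idata, method="bulk")
        ess_tail = az.ess(idata, method="tail")
    rows = []
    for name in draws:
        r = np.atleast_1d(np.asarray(rhat[name])).ravel()
        eb = np.atleast_1d(np.asarray(ess_bulk[name])).ravel()
        et = np.atleast_1d(np.asarray(ess_tail[name])).ravel()
        rows.append(
            {
                "parameter": name,
                "max_rhat": float(np.nanmax(r)),
                "min_ess_bulk": float(np.nanmin(eb)),
                "min_ess_tail": float(np.nanmin(et)),
            }
        )
    table = pd.DataFrame(rows)
    n_div = int(divergences.sum())
    n_total = int(divergences.size)
    passed = bool(
        (table["max_rhat"] < RHAT_MAX).all()
        and (table["min_ess_bulk"] > ESS_MIN).all()
        and (table["min_ess_tail"] > ESS_MIN).all()
        and n_div / max(n_total, 1) < DIVERGENCE_RATE_MAX
    )
    return table, passed


def make_posterior(
    raw: RawChains, unpack: Callable[[np.ndarray], dict[str, np.ndarray]],
    notes: dict | None = None,
) -> PosteriorDraws:
    """Transform raw unconstrained chains into named constrained draws."""
    chains, n_samples, _ = raw.positions.shape
    example = unpack(raw.positions[0, 0])
    draws = {
        name: np.empty((chains, n_samples) + np.shape(val))
        for name, val in example.items()
    }
    for c in range(chains):
        for it in range(n_samples):
            for name, val in unpack(raw.positions[c, it]).items():
                draws[name][c, it] = val
    table, passed = diagnose(draws, raw.divergences)
    return PosteriorDraws(
        draws=draws,
        diagnostics=table,
        n_divergent=int(raw.divergences.sum()),
        n_iterations=int(raw.divergences.size),
        passed=passed,
        notes=notes or {},
    )


def write_draws_csv(post: PosteriorDraws, path) -> None:
    """Long-format CSV: chain, iteration, parameter, value."""
    frames = []
    for name, arr in post.draws.items():
        chains, iters = arr.shape[:2]
        flat = arr.reshape(chains, iters, -1)
        for k in range(flat.shape[2]):
            label = name if flat.shape[2] == 1 else f"{name}[{k}]"
            idx = pd.MultiIndex.from_product(
                [range(chains), range(iters)], names=["chain", "iteration"]
            )
            frames.append(
                pd.DataFrame(
                    {"parameter": label, "value": flat[:, :, k].ravel()}, index=idx
                )
            )
    pd.concat(frames).reset_index().to_csv(path, index=False)
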
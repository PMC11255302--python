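"""Population-based optimizers behind a single minimize-this-fitness contract.

Four swarm metaheuristics are provided — elephant herding (EHO), particle
swarm (PSO), firefly, and flower pollination (FPO) with Mantegna Lévy
flights.  All of them

* minimize a scalar fitness over a box ``[lower, upper]^d``,
* clamp every emitted position into the box,
* keep an elitist archive so the reported best fitness is non-increasing,
* stop after ``max_iter`` iterations or once the best fitness drops to
  ``mse_tol`` (classifier callers pass a mean-squared-error fitness, hence
  the name), and
* are bit-reproducible under a given integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Bounds",
    "Population",
    "EHOParams",
    "PSOParams",
    "FireflyParams",
    "FPOParams",
    "LevySampler",
    "OptimizerError",
    "eho_optimize",
    "pso_optimize",
    "firefly_optimize",
    "fpo_optimize",
    "levy_sample",
    "mantegna_sigma",
]

FitnessFn = Callable[[np.ndarray], float]


class OptimizerError(RuntimeError):
    """Raised when a fitness evaluation returns a non-finite value."""

    def __init__(self, message: str, position: np.ndarray | None = None):
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Bounds:
    """Elementwise box constraints of the search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or not np.all(lo < hi):
            raise ValueError("bounds require lower < upper elementwise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))


@dataclass
class Population:
    """Final optimizer state: positions, fitnesses and the elitist best."""

    positions: np.ndarray
    fitnesses: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    trace: np.ndarray  # best fitness after each iteration (index 0 = init)
    n_evals: int = 0


@dataclass(frozen=True)
class EHOParams:
    """Elephant-herding controls: Υ scales the pull toward the working best,
    δ scales the herd-centre replacement of that best."""

    gamma_control: float = 0.5
    delta_control: float = 0.5
    population: int = 30
    max_iter: int = 100
    mse_tol: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma_control <= 1.0 and 0.0 <= self.delta_control <= 1.0):
            raise ValueError("EHO control scalars must lie in [0, 1]")


@dataclass(frozen=True)
class PSOParams:
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    population: int = 200
    max_iter: int = 1000
    mse_tol: float = 1e-7


@dataclass(frozen=True)
class FireflyParams:
    i0: float = 1.0
    gamma_absorb: float = 0.1
    beta_attract: float = 0.6
    alpha_rand: float = 0.1
    population: int = 200
    max_iter: int = 1000
    mse_tol: float = 1e-7


@dataclass(frozen=True)
class FPOParams:
    step_delta: float = 0.15
    levy_lambda: float = 1.5
    switch_prob: float = 0.65
    population: int = 200
    max_iter: int = 1000
    mse_tol: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.switch_prob <= 1.0):
            raise ValueError("switch_prob must lie in [0, 1]")
        if not (1.0 < self.levy_lambda <= 2.0):
            raise ValueError("levy_lambda must lie in (1, 2]")


# ---------------------------------------------------------------------------
# Lévy flights (Mantegna)
# ---------------------------------------------------------------------------

def mantegna_sigma(lam: float) -> float:
    """Mantegna scale σ for the numerator Gaussian of a Lévy step.

    σ = { Γ(1+λ)·sin(πλ/2) / (Γ((1+λ)/2)·λ·2^((λ−1)/2)) }^(1/λ); for λ=1.5
    this evaluates to ≈ 0.6966.
    """
    if not (1.0 < lam <= 2.0):
        raise ValueError("levy exponent must lie in (1, 2]")
    num = math.gamma(1.0 + lam) * math.sin(math.pi * lam / 2.0)
    den = math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    return (num / den) ** (1.0 / lam)


@dataclass
class LevySampler:
    """Heavy-tailed step sampler s = U / |V|^(1/λ), U~N(0,σ²), V~N(0,1)."""

    lam: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma = mantegna_sigma(self.lam)  # validates lam
        self._rng = np.random.default_rng(self.seed)

    def draw(self, count: int, rng: np.random.Generator | None = None) -> np.ndarray:
        r = self._rng if rng is None else rng
        u = r.normal(0.0, self.sigma, size=count)
        v = r.normal(0.0, 1.0, size=count)
        return u / np.abs(v) ** (1.0 / self.lam)


def levy_sample(sampler: LevySampler, count: int) -> np.ndarray:
    """Draw ``count`` Lévy step sizes from the sampler's own seeded stream."""
    return sampler.draw(count)


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

def _evaluate(fitness: FitnessFn, x: np.ndarray) -> float:
    val = float(fitness(x))
    if not math.isfinite(val):
        raise OptimizerError(f"fitness returned non-finite value {val}", position=x)
    return val


def _init_state(
    fitness: FitnessFn,
    bounds: Bounds,
    n: int,
    rng: np.random.Generator,
    init_positions: np.ndarray | None,
):
    if init_positions is not None:
        pos = bounds.clip(np.asarray(init_positions, dtype=float).copy())
        if pos.shape != (n, bounds.dim):
            raise ValueError(
                f"init_positions shape {pos.shape} != ({n}, {bounds.dim})"
            )
    else:
        pos = bounds.sample(rng, n)
    fit = np.array([_evaluate(fitness, p) for p in pos])
    best_i = int(np.argmin(fit))
    return pos, fit, pos[best_i].copy(), float(fit[best_i])


def _finish(pos, fit, best_pos, best_fit, it, trace, n_evals) -> Population:
    return Population(
        positions=pos,
        fitnesses=fit,
        best_position=best_pos,
        best_fitness=best_fit,
        iteration=it,
        trace=np.asarray(trace, dtype=float),
        n_evals=n_evals,
    )


# ---------------------------------------------------------------------------
# Elephant herding optimization
# ---------------------------------------------------------------------------

def eho_optimize(
    fitness: FitnessFn,
    bounds: Bounds,
    params: EHOParams = EHOParams(),
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> Population:
    """Single-herd elephant herding optimization.

    Per iteration every individual moves toward the working attractor
    ``p_best`` by ``p += Υ·rand1·(p_best − p)`` with a fresh ``rand1`` per
    individual; the attractor is then replaced by ``δ · p_center`` (the herd
    mean), and the worst-fitness individual is re-seeded uniformly over
    ``p_min + (p_max − p_min + 1)·rand`` then clamped into the bounds.  The
    elitist archive (``best_position`` / ``best_fitness``) tracks the true
    best ever evaluated, so the reported trace is monotone even though the
    working attractor may regress.
    """
    rng = np.random.default_rng(seed)
    n = params.population
    pos, fit, best_pos, best_fit, = _init_state(fitness, bounds, n, rng, init_positions)
    n_evals = n
    trace = [best_fit]
    p_best = best_pos.copy()  # working attractor, overwritten by δ·center

    it = 0
    for it in range(1, params.max_iter + 1):
        if best_fit <= params.mse_tol:
            break
        for i in range(n):
            r1 = rng.uniform()
            pos[i] = bounds.clip(
                pos[i] + params.gamma_control * (p_best - pos[i]) * r1
            )
            fit[i] = _evaluate(fitness, pos[i])
            n_evals += 1
            if fit[i] < best_fit:
                best_fit, best_pos = float(fit[i]), pos[i].copy()
        # attractor update from the herd centre
        p_best = params.delta_control * pos.mean(axis=0)
        # re-seed the worst individual
        worst = int(np.argmax(fit))
        raw = bounds.lower + (bounds.upper - bounds.lower + 1.0) * rng.uniform(
            size=bounds.dim
        )
        pos[worst] = bounds.clip(raw)
        fit[worst] = _evaluate(fitness, pos[worst])
        n_evals += 1
        if fit[worst] < best_fit:
            best_fit, best_pos = float(fit[worst]), pos[worst].copy()
        trace.append(best_fit)
    return _finish(pos, fit, best_pos, best_fit, it, trace, n_evals)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------

def pso_optimize(
    fitness: FitnessFn,
    bounds: Bounds,
    params: PSOParams = PSOParams(),
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> Population:
    """Inertia-weight PSO: ``v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)``
    with fresh ``r1, r2`` per individual per iteration, then ``x ← x + v``
    clamped into the bounds.  pbest/gbest update on strict improvement."""
    rng = np.random.default_rng(seed)
    n = params.population
    pos, fit, best_pos, best_fit = _init_state(fitness, bounds, n, rng, init_positions)
    n_evals = n
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_fit = fit.copy()
    trace = [best_fit]

    it = 0
    for it in range(1, params.max_iter + 1):
        if best_fit <= params.mse_tol:
            break
        for i in range(n):
            r1, r2 = rng.uniform(), rng.uniform()
            vel[i] = (
                params.w * vel[i]
                + params.c1 * r1 * (pbest[i] - pos[i])
                + params.c2 * r2 * (best_pos - pos[i])
            )
            pos[i] = bounds.clip(pos[i] + vel[i])
            fit[i] = _evaluate(fitness, pos[i])
            n_evals += 1
            if fit[i] < pbest_fit[i]:
                pbest_fit[i], pbest[i] = fit[i], pos[i].copy()
                if fit[i] < best_fit:
                    best_fit, best_pos = float(fit[i]), pos[i].copy()
        trace.append(best_fit)
    return _finish(pos, fit, best_pos, best_fit, it, trace, n_evals)


# ---------------------------------------------------------------------------
# Firefly algorithm
# ---------------------------------------------------------------------------

def firefly_optimize(
    fitness: FitnessFn,
    bounds: Bounds,
    params: FireflyParams = FireflyParams(),
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> Population:
    """Firefly algorithm with brightness = −fitness (minimization).

    For each firefly *i*, every strictly brighter firefly *j* attracts it by
    ``β·exp(−γ·r_ij²)·(x_j − x_i)`` (applied sequentially, ascending index,
    positions updated in place); one random perturbation ``α·(rand − 0.5)``
    per dimension is then added per iteration, so two equally bright
    fireflies only random-walk.  As γ→∞ the attraction vanishes and the
    algorithm degenerates to a pure bounded random walk.
    """
    rng = np.random.default_rng(seed)
    n = params.population
    pos, fit, best_pos, best_fit = _init_state(fitness, bounds, n, rng, init_positions)
    n_evals = n
    trace = [best_fit]

    it = 0
    for it in range(1, params.max_iter + 1):
        if best_fit <= params.mse_tol:
            break
        brightness = -fit
        for i in range(n):
            moved = pos[i].copy()
            for j in range(n):
                if brightness[j] > brightness[i]:
                    r2 = float(np.sum((pos[j] - moved) ** 2))
                    moved = moved + params.beta_attract * params.i0 * math.exp(
                        -params.gamma_absorb * r2
                    ) * (pos[j] - moved)
            moved = moved + params.alpha_rand * (rng.uniform(size=bounds.dim) - 0.5)
            pos[i] = bounds.clip(moved)
            fit[i] = _evaluate(fitness, pos[i])
            n_evals += 1
            if fit[i] < best_fit:
                best_fit, best_pos = float(fit[i]), pos[i].copy()
        trace.append(best_fit)
    return _finish(pos, fit, best_pos, best_fit, it, trace, n_evals)


# ---------------------------------------------------------------------------
# Flower pollination optimization
# ---------------------------------------------------------------------------

def fpo_optimize(
    fitness: FitnessFn,
    bounds: Bounds,
    params: FPOParams = FPOParams(),
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> Population:
    """Flower pollination with Lévy-flight global steps and greedy acceptance.

    Per individual per iteration: with probability ρ take a global
    (biotic) pollination step ``x + δ·L ⊙ (g_best − x)`` with one Mantegna
    Lévy draw per dimension, otherwise a local (abiotic) random-walk step
    ``x + ε·(x_j − x_k)`` with ε ~ U[0,1] and j, k drawn without replacement
    from the other individuals.  A move is kept only if it improves the
    individual's fitness.  ``step_counts`` on the returned population records
    how many global/local steps were taken.
    """
    rng = np.random.default_rng(seed)
    n = params.population
    if n < 3:
        raise ValueError("FPO needs a population of at least 3 (i, j, k distinct)")
    sampler = LevySampler(lam=params.levy_lambda, seed=0)
    pos, fit, best_pos, best_fit = _init_state(fitness, bounds, n, rng, init_positions)
    n_evals = n
    trace = [best_fit]
    counts = {"global": 0, "local": 0}

    it = 0
    for it in range(1, params.max_iter + 1):
        if best_fit <= params.mse_tol:
            break
        for i in range(n):
            if rng.uniform() < params.switch_prob:
                step = sampler.draw(bounds.dim, rng=rng)
                cand = pos[i] + params.step_delta * step * (best_pos - pos[i])
                counts["global"] += 1
            else:
                others = [k for k in range(n) if k != i]
                j, k = rng.choice(others, size=2, replace=False)
                eps = rng.uniform()
                cand = pos[i] + eps * (pos[j] - pos[k])
                counts["local"] += 1
            cand = bounds.clip(cand)
            cand_fit = _evaluate(fitness, cand)
            n_evals += 1
            if cand_fit < fit[i]:  # greedy acceptance
                pos[i], fit[i] = cand, cand_fit
                if cand_fit < best_fit:
                    best_fit, best_pos = float(cand_fit), cand.copy()
        trace.append(best_fit)
    result = _finish(pos, fit, best_pos, best_fit, it, trace, n_evals)
    result.step_counts = counts  # type: ignore[attr-defined]
    return result
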
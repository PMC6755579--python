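"""Chaos-embedded particle swarm global search with two-stage BFGS refinement.

The global optimizer is a canonical PSO: each particle carries a position
``X`` and velocity ``V`` in the D-dimensional search space and is pulled
toward its personal best (pbest) and the swarm best (gbest),

    V(t+1) = w V(t) + c1 r1 (pbest - X) + c2 r2 (gbest - X)
    X(t+1) = X(t) + V(t+1).

In chaos-embedded mode the inertia weight and the acceleration randomness
are replaced by two independent chaotic streams per particle, drawn once
per particle per generation and coupled so the cognitive and social
weights sum to one:

    V(t+1) = w_cm V(t) + c1 r_cm (pbest - X) + c2 (1 - r_cm) (gbest - X).

Each position update is refined by a two-stage BFGS local search (2LS): a
short probe with a fraction R of the full step budget gates the expensive
full-budget refinement, which runs only when the probe already beats the
particle's pbest. The search terminates when gbest has stalled for Cr
consecutive generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chaoticmaps import ChaoticStream

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "BoxObjective",
    "velocity_update_standard",
    "velocity_update_chaotic",
    "position_update",
    "bfgs_local_search",
    "two_stage_local_search",
    "pso_search",
]

#: gbest improvement below this (kcal/mol or objective units) counts as a stall
STALL_TOL = 1e-4


@dataclass
class SwarmConfig:
    """PSO and 2LS settings (defaults follow the docking parameterization).

    ``n_particles`` is 8 for pose prediction and typically raised to 16 for
    screening; ``ls_ratio`` (R) is the stage-1 fraction of the local-search
    step budget and ``stall_generations`` (Cr) the number of consecutive
    non-improving generations that triggers termination.
    """

    n_particles: int = 8
    inertia: float = 0.36
    cognitive: float = 0.99
    social: float = 0.99
    chaos_map: str | None = "singer"
    ls_ratio: float = 0.1
    stall_generations: int = 18
    max_generations: int = 200
    full_ls_steps: int | None = None  # default 10*D + 30
    two_stage: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0.0 < self.ls_ratio <= 1.0:
            raise ValueError("ls_ratio must lie in (0, 1]")
        if self.stall_generations < 1:
            raise ValueError("stall_generations must be >= 1")
        if self.chaos_map in ("none", ""):
            self.chaos_map = None

    def baseline(self) -> "SwarmConfig":
        """Stock-PSO comparison mode: uniform randomness, one-stage search."""
        return replace(self, chaos_map=None, two_stage=False)


@dataclass
class Particle:
    X: np.ndarray
    V: np.ndarray
    pbest_X: np.ndarray
    pbest_score: float
    w_stream: ChaoticStream | None = None
    r_stream: ChaoticStream | None = None


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_X: np.ndarray
    gbest_score: float
    generation: int = 0
    stall_count: int = 0


class BoxObjective:
    """Minimal objective over an axis-aligned box; subclasses override
    :meth:`value` and :meth:`gradient`.

    The optimizer only relies on this interface: ``dim``, ``lower`` /
    ``upper`` bounds, ``value``, ``sanitize`` (project a proposal back into
    the feasible set), ``random_point``, ``vmax`` (per-component velocity
    clamp) and ``local_chart`` (the coordinates BFGS works in).
    """

    def __init__(self, dim: int, lower, upper):
        self.dim = int(dim)
        self.lower = np.broadcast_to(np.asarray(lower, float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(upper, float), (self.dim,)).copy()
        if np.any(self.upper <= self.lower):
            raise ValueError("upper bounds must exceed lower bounds")

    def value(self, x) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:
        return _finite_difference(self.value, np.asarray(x, float))

    def sanitize(self, x) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def random_point(self, rng) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)

    def vmax(self) -> np.ndarray:
        return 0.5 * (self.upper - self.lower)

    def local_chart(self, x):
        """(s0, fun, grad, to_x): identity chart for plain vector spaces."""
        return np.asarray(x, float).copy(), self.value, self.gradient, lambda s: s


def _finite_difference(fun, x, h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h)
    return g


# ---------------------------------------------------------------------------
# velocity / position updates
# ---------------------------------------------------------------------------

def velocity_update_standard(p: Particle, gbest_X, cfg: SwarmConfig,
                             r1: float, r2: float) -> np.ndarray:
    """Canonical PSO velocity with constant inertia and uniform r1, r2."""
    return (
        cfg.inertia * p.V
        + cfg.cognitive * r1 * (p.pbest_X - p.X)
        + cfg.social * r2 * (gbest_X - p.X)
    )


def velocity_update_chaotic(p: Particle, gbest_X, cfg: SwarmConfig) -> np.ndarray:
    """Chaos-embedded velocity update.

    Draws one inertia value and one acceleration value from the particle's
    two chaotic streams (once per particle per generation; the same
    scalars apply to all D components), with the cognitive and social
    random weights coupled as r_cm and 1 - r_cm.
    """
    w_cm = p.w_stream.next_unit()
    r_cm = p.r_stream.next_unit()
    return (
        w_cm * p.V
        + cfg.cognitive * r_cm * (p.pbest_X - p.X)
        + cfg.social * (1.0 - r_cm) * (gbest_X - p.X)
    )


def position_update(p: Particle, v_new, objective) -> np.ndarray:
    """X' = X + V', projected back into the feasible set."""
    return objective.sanitize(p.X + np.asarray(v_new))


# ---------------------------------------------------------------------------
# BFGS local search
# ---------------------------------------------------------------------------

def bfgs_local_search(fun, grad, x0, max_steps: int, gtol: float = 1e-6,
                      max_step_norm: float = 2.0):
    """Quasi-Newton descent with Armijo backtracking line search.

    Proposed steps are capped at ``max_step_norm`` (trust-region style;
    gradients near steric walls are huge and would otherwise waste the
    whole backtracking budget). Returns ``(x, f, n_steps)`` with
    ``f <= fun(x0)``; a non-finite objective at the start aborts and
    returns the input unchanged.
    """
    x, f, _, steps = _bfgs(fun, grad, x0, max_steps, gtol, max_step_norm)
    return x, f, steps


def _bfgs(fun, grad, x0, max_steps: int, gtol: float = 1e-6,
          max_step_norm: float = 2.0, f0=None, g0=None):
    """BFGS core; ``f0``/``g0`` resume a search without re-evaluating.

    Returns ``(x, f, g, n_steps)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = float(fun(x)) if f0 is None else float(f0)
    if not math.isfinite(f):
        return x, f, None, 0
    g = np.asarray(grad(x) if g0 is None else g0, dtype=float)
    n = x.size
    H = np.eye(n)
    steps = 0
    alpha_prev = 1.0
    for _ in range(max_steps):
        if not np.all(np.isfinite(g)) or np.linalg.norm(g) < gtol:
            break
        p = -(H @ g)
        pnorm = float(np.linalg.norm(p))
        if pnorm > max_step_norm:
            p *= max_step_norm / pnorm
        slope = float(p @ g)
        if slope >= 0.0:  # lost positive-definiteness; restart on gradient
            H = np.eye(n)
            p = -g
            pnorm = float(np.linalg.norm(p))
            if pnorm > max_step_norm:
                p *= max_step_norm / pnorm
            slope = float(p @ g)
        alpha, accepted = min(1.0, 4.0 * alpha_prev), False
        for _ in range(30):
            xn = x + alpha * p
            fn = float(fun(xn))
            if math.isfinite(fn) and fn <= f + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        alpha_prev = alpha
        gn = np.asarray(grad(xn), dtype=float)
        s = xn - x
        y = gn - g
        sy = float(s @ y)
        if sy > 1e-10:
            rho = 1.0 / sy
            Hy = H @ y
            H = (
                H
                - rho * (np.outer(s, Hy) + np.outer(Hy, s))
                + rho * rho * float(y @ Hy) * np.outer(s, s)
                + rho * np.outer(s, s)
            )
        x, f, g = xn, fn, gn
        steps += 1
    return x, f, g, steps


def _finalize(objective, to_x, s, f):
    """Map a chart point back to the search space; re-score if the
    projection into the box moved it."""
    raw = to_x(s)
    xn = objective.sanitize(raw)
    if not np.array_equal(xn, raw):
        f = float(objective.value(xn))
    return xn, f


def two_stage_local_search(p: Particle, objective, cfg: SwarmConfig,
                           full_steps: int) -> bool:
    """2LS refinement of a freshly position-updated particle.

    Stage 1 probes with ``max(1, round(R * full_steps))`` BFGS steps; only
    if the probe already beats the particle's stored pbest does stage 2
    spend the remaining budget continuing the same search, after which
    pbest (and the particle) move to the refined solution. A gated-out
    particle keeps its position-updated X. Returns True when pbest
    improved.
    """
    s0, fun, grad, to_x = objective.local_chart(p.X)
    stage1 = max(1, round(cfg.ls_ratio * full_steps))
    s1, f1, g1, _ = _bfgs(fun, grad, s0, stage1)
    if not (f1 < p.pbest_score):
        return False
    remaining = full_steps - stage1
    if remaining > 0 and g1 is not None:
        s2, f2, _, _ = _bfgs(fun, grad, s1, remaining, f0=f1, g0=g1)
    else:
        s2, f2 = s1, f1
    x2, f2 = _finalize(objective, to_x, s2, f2)
    p.X = x2
    if f2 < p.pbest_score:
        p.pbest_X = x2.copy()
        p.pbest_score = f2
        return True
    return False


def one_stage_local_search(p: Particle, objective, cfg: SwarmConfig,
                           full_steps: int) -> bool:
    """Full-budget refinement of every particle (classic one-stage PSO
    docking baseline; see :meth:`SwarmConfig.baseline`)."""
    s0, fun, grad, to_x = objective.local_chart(p.X)
    s1, f1, _, _ = _bfgs(fun, grad, s0, full_steps)
    x1, f1 = _finalize(objective, to_x, s1, f1)
    p.X = x1
    if f1 < p.pbest_score:
        p.pbest_X = x1.copy()
        p.pbest_score = f1
        return True
    return False


# ---------------------------------------------------------------------------
# the swarm search
# ---------------------------------------------------------------------------

def pso_search(objective, cfg: SwarmConfig, seed: int | None = None,
               history: list | None = None):
    """Run the (optionally chaos-embedded) PSO with 2LS refinement.

    The swarm is initialized uniformly inside the feasible set (the
    initialization sweep counts as generation 1) and iterates velocity /
    position updates plus local search until gbest has failed to improve
    by more than ``STALL_TOL`` for ``stall_generations`` consecutive
    generations, or ``max_generations`` is reached.

    ``history``, if given, collects ``(generation, gbest_score)`` pairs.
    Returns ``(gbest_X, gbest_score, n_generations)``.
    """
    if seed is None:
        seed = cfg.seed
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    ss_init, ss_streams, ss_draws = master.spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_draws = np.random.default_rng(ss_draws)
    stream_seeds = ss_streams.spawn(2 * cfg.n_particles)

    D = objective.dim
    full_steps = cfg.full_ls_steps or (10 * D + 30)
    vmax = objective.vmax()

    particles: list[Particle] = []
    for i in range(cfg.n_particles):
        x = objective.sanitize(objective.random_point(rng_init))
        f = float(objective.value(x))
        w_stream = r_stream = None
        if cfg.chaos_map is not None:
            w_stream = ChaoticStream(cfg.chaos_map, seed=np.random.default_rng(stream_seeds[2 * i]))
            r_stream = ChaoticStream(cfg.chaos_map, seed=np.random.default_rng(stream_seeds[2 * i + 1]))
        particles.append(
            Particle(X=x, V=np.zeros(D), pbest_X=x.copy(), pbest_score=f,
                     w_stream=w_stream, r_stream=r_stream)
        )

    best = min(particles, key=lambda p: p.pbest_score)
    state = SwarmState(
        particles=particles,
        gbest_X=best.pbest_X.copy(),
        gbest_score=best.pbest_score,
        generation=1,
        stall_count=0,
    )

    local_search = two_stage_local_search if cfg.two_stage else one_stage_local_search
    if history is not None:
        history.append((state.generation, state.gbest_score))

    while state.generation < cfg.max_generations:
        state.generation += 1
        previous_best = state.gbest_score
        for p in particles:
            if cfg.chaos_map is not None:
                v_new = velocity_update_chaotic(p, state.gbest_X, cfg)
            else:
                r1, r2 = rng_draws.uniform(size=2)
                v_new = velocity_update_standard(p, state.gbest_X, cfg, r1, r2)
            p.V = np.clip(v_new, -vmax, vmax)
            p.X = position_update(p, p.V, objective)
            if local_search(p, objective, cfg, full_steps):
                if p.pbest_score < state.gbest_score:
                    state.gbest_score = p.pbest_score
                    state.gbest_X = p.pbest_X.copy()
        if state.gbest_score < previous_best - STALL_TOL:
            state.stall_count = 0
        else:
            state.stall_count += 1
        if history is not None:
            history.append((state.generation, state.gbest_score))
        if state.stall_count >= cfg.stall_generations:
            break
    return state.gbest_X, state.gbest_score, state.generation
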
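"""Chaotic maps as deterministic drop-in random streams.

Five classic one-dimensional (plus one two-dimensional) chaotic maps —
logistic, Singer, sinusoidal, tent and Zaslavskii — are provided both as
bare step functions and as stateful :class:`ChaoticStream` objects that
behave like a random number generator producing values in (0, 1).

Chaotic sequences are deterministic, bounded, ergodic within their
admissible range and extremely sensitive to the initial state, which makes
them attractive replacements for pseudo-random draws inside stochastic
optimizers: a trajectory tends to cover its range without repeating.

Parameters default to the chaotic-regime values used throughout the
package: logistic alpha=4, Singer mu=1.07, sinusoidal alpha=2.3,
Zaslavskii v=400, r=3, a=12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAP_NAMES",
    "ChaoticMapParams",
    "ChaoticStream",
    "logistic_step",
    "singer_step",
    "sinusoidal_step",
    "tent_step",
    "zaslavskii_step",
    "map_trajectory",
]

MAP_NAMES = ("logistic", "singer", "sinusoidal", "tent", "zaslavskii")

# Known exact fixed points (or short pre-periodic points collapsing onto
# them) per map; landing within _FP_TOL of one kills the chaos in floating
# point, so the stream re-seeds instead.
_FIXED_POINTS = {
    "logistic": (0.0, 0.25, 0.5, 0.75, 1.0),
    "singer": (0.0,),
    "sinusoidal": (0.0,),
    "tent": (0.0,),
    "zaslavskii": (),
}
_FP_TOL = 1e-12


@dataclass
class ChaoticMapParams:
    """Control parameters for one chaotic map (chaotic-regime defaults)."""

    map_name: str
    alpha: float = 4.0  # logistic; 2.3 for sinusoidal
    mu: float = 1.07  # Singer
    v: float = 400.0  # Zaslavskii
    r: float = 3.0
    a: float = 12.0

    @classmethod
    def defaults(cls, map_name: str) -> "ChaoticMapParams":
        if map_name not in MAP_NAMES:
            raise ValueError(
                f"unknown chaotic map {map_name!r}; expected one of {MAP_NAMES}"
            )
        alpha = 2.3 if map_name == "sinusoidal" else 4.0
        return cls(map_name=map_name, alpha=alpha)


def logistic_step(x: float, alpha: float = 4.0) -> float:
    """One iterate of the logistic map x' = alpha*x*(1-x)."""
    return alpha * x * (1.0 - x)


def singer_step(x: float, mu: float = 1.07) -> float:
    """One iterate of the Singer map (quartic polynomial recurrence)."""
    return mu * (7.86 * x - 23.31 * x**2 + 28.75 * x**3 - 13.302875 * x**4)


def sinusoidal_step(x: float, alpha: float = 2.3) -> float:
    """One iterate of the sinusoidal map x' = alpha*x^2*sin(pi*x)."""
    return alpha * x * x * math.sin(math.pi * x)


def tent_step(x: float) -> float:
    """One iterate of the tent map in its optimization-task form."""
    if x < 0.7:
        return x / 0.7
    return (10.0 / 3.0) * (1.0 - x)


def zaslavskii_step(
    x: float,
    y: float,
    v: float = 400.0,
    r: float = 3.0,
    a: float = 12.0,
) -> tuple[float, float]:
    """One iterate of the Zaslavskii map.

    The auxiliary state is advanced first, y' = cos(2*pi*x) + exp(-r)*y,
    and then folded into the unit-interval state, x' = (x + v + a*y') mod 1.
    Returns ``(x', y')``.
    """
    y_new = math.cos(2.0 * math.pi * x) + math.exp(-r) * y
    x_new = (x + v + a * y_new) % 1.0
    return x_new, y_new


class ChaoticStream:
    """Stateful chaotic sequence usable as a random stream on (0, 1).

    The stream starts from a random admissible initial state (drawn with a
    seedable RNG from the map's chaotic start set) and advances one map
    iterate per :meth:`next_unit` call. Degenerate states — iterates that
    leave (0, 1) or land on a fixed point, where the floating-point orbit
    would collapse — are handled by transparently re-seeding from the
    admissible set and stepping again, so every returned value lies
    strictly in (0, 1).

    Parameters
    ----------
    params : ChaoticMapParams or str
        Map selection (a bare map name selects chaotic-regime defaults).
    seed : int, numpy Generator or None
        Source of randomness for (re-)initialization.
    x0, y0 : float, optional
        Explicit initial state, overriding the random draw (useful for
        reproducing a specific trajectory).
    """

    def __init__(self, params, seed=None, x0: float | None = None, y0: float = 0.0):
        if isinstance(params, str):
            params = ChaoticMapParams.defaults(params)
        if params.map_name not in MAP_NAMES:
            raise ValueError(f"unknown chaotic map {params.map_name!r}")
        self.params = params
        self.rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator
        ) else seed
        self.y = float(y0)
        self.x = float(x0) if x0 is not None else self._draw_start()

    def _draw_start(self) -> float:
        """Uniform draw from the map's admissible chaotic start set."""
        name = self.params.map_name
        if name == "sinusoidal":
            return float(self.rng.uniform(0.45, 0.92))
        if name == "zaslavskii":
            self.y = 0.0
            return float(self.rng.uniform(0.0, 1.0))
        # logistic / singer / tent: open unit interval, away from the
        # logistic pre-periodic points {0.25, 0.5, 0.75}
        while True:
            x = float(self.rng.uniform(0.0, 1.0))
            if not 0.0 < x < 1.0:
                continue
            if name == "logistic" and any(
                abs(x - fp) < 1e-9 for fp in (0.25, 0.5, 0.75)
            ):
                continue
            return x

    def _step(self) -> float:
        p = self.params
        if p.map_name == "logistic":
            return logistic_step(self.x, p.alpha)
        if p.map_name == "singer":
            return singer_step(self.x, p.mu)
        if p.map_name == "sinusoidal":
            return sinusoidal_step(self.x, p.alpha)
        if p.map_name == "tent":
            return tent_step(self.x)
        x_new, self.y = zaslavskii_step(self.x, self.y, p.v, p.r, p.a)
        return x_new

    def next_unit(self) -> float:
        """Advance one step and return the new state, strictly in (0, 1)."""
        fps = _FIXED_POINTS[self.params.map_name]
        for _ in range(100):
            x_new = self._step()
            degenerate = (
                not 0.0 < x_new < 1.0
                or not math.isfinite(x_new)
                or any(abs(x_new - fp) < _FP_TOL for fp in fps)
            )
            if not degenerate:
                self.x = x_new
                return x_new
            self.x = self._draw_start()
        raise RuntimeError(
            f"chaotic stream for {self.params.map_name!r} failed to produce a "
            "non-degenerate value after 100 re-seeds"
        )


def map_trajectory(
    map_name: str,
    x0,
    n_steps: int,
    params: ChaoticMapParams | None = None,
    burn_in: int = 0,
    return_y: bool = False,
):
    """Vectorized raw trajectories of one map (no degeneracy re-seeding).

    Iterates the bare map recurrence ``n_steps`` times from one or more
    initial states ``x0`` (after discarding ``burn_in`` iterates) and
    returns an array of shape ``(n_steps, len(x0))``. For the Zaslavskii
    map, ``return_y=True`` additionally returns the auxiliary-state
    trajectory. Used for regime diagnostics (range coverage, bounds).
    """
    if params is None:
        params = ChaoticMapParams.defaults(map_name)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    y = np.zeros_like(x)
    out = np.empty((n_steps, x.size))
    ys = np.empty((n_steps, x.size)) if return_y else None

    def step(x, y):
        if map_name == "logistic":
            return params.alpha * x * (1.0 - x), y
        if map_name == "singer":
            return (
                params.mu
                * (7.86 * x - 23.31 * x**2 + 28.75 * x**3 - 13.302875 * x**4),
                y,
            )
        if map_name == "sinusoidal":
            return params.alpha * x * x * np.sin(np.pi * x), y
        if map_name == "tent":
            return np.where(x < 0.7, x / 0.7, (10.0 / 3.0) * (1.0 - x)), y
        if map_name == "zaslavskii":
            y_new = np.cos(2.0 * np.pi * x) + np.exp(-params.r) * y
            return (x + params.v + params.a * y_new) % 1.0, y_new
        raise ValueError(f"unknown chaotic map {map_name!r}")

    for _ in range(burn_in):
        x, y = step(x, y)
    for i in range(n_steps):
        x, y = step(x, y)
        out[i] = x
        if return_y:
            ys[i] = y
    if return_y:
        return out, ys
    return out
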
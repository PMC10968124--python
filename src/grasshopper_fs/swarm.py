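"""Continuous grasshopper swarm dynamics.

The swarm moves under pairwise social forces ``S(r) = f*exp(-r/l) - exp(-r)``
(repulsive at short range, attractive at long range, zero at the comfort-zone
boundary, ~2.079 for f=0.5, l=1.5) plus attraction toward the incumbent best
solution (the target).  A comfort coefficient ``c`` shrinks linearly over the
run and damps the social term, switching the swarm from exploration to
exploitation.  Pairwise distances are affinely normalized into [1, 4] before
being fed to the force function so that every pair sits in the range where
both attraction and repulsion occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect
from scipy.spatial.distance import cdist

from .config import GOAConfig

__all__ = [
    "SwarmState",
    "social_force",
    "comfort_coefficient",
    "comfort_zone_boundary",
    "normalize_distances",
    "goa_step",
]


@dataclass
class SwarmState:
    """Positions, masks and fitness of the swarm plus the incumbent target."""

    positions: np.ndarray          # (N, D) continuous coordinates
    masks: np.ndarray              # (N, D) bits in {0, 1}
    fitness: np.ndarray            # (N,)
    target_position: np.ndarray    # (D,)
    target_mask: np.ndarray        # (D,)
    target_fitness: float
    iteration: int = 0


def social_force(r, f: float = 0.5, l: float = 1.5):
    """Social force between two grasshoppers at normalized distance ``r``.

    Negative values are repulsion, positive attraction; the force vanishes at
    the comfort-zone boundary.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("distance r must be finite")
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    if f <= 0 or l <= 0:
        raise ValueError("f and l must be positive")
    out = f * np.exp(-r / l) - np.exp(-r)
    return float(out) if out.ndim == 0 else out


def comfort_zone_boundary(f: float = 0.5, l: float = 1.5,
                          bracket: tuple[float, float] = (0.1, 4.0),
                          xtol: float = 1e-4) -> float:
    """Distance at which the social force changes sign, by bisection."""
    return float(bisect(lambda r: social_force(r, f, l), *bracket, xtol=xtol))


def comfort_coefficient(iteration: int, max_iterations: int,
                        c_max: float = 1.0, c_min: float = 1e-5) -> float:
    """Linearly decaying comfort coefficient c, from c_max (iter 0) to c_min (iter L)."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not 0 <= iteration <= max_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {max_iterations}]")
    t = iteration / max_iterations
    return (1.0 - t) * c_max + t * c_min    # lerp form: endpoint-exact


def normalize_distances(pairwise: np.ndarray) -> np.ndarray:
    """Affinely map off-diagonal pairwise distances into [1, 4].

    The minimum off-diagonal distance maps to 1 and the maximum to 4; the
    diagonal is left at 0 (never consumed).  If every off-diagonal distance is
    equal (e.g. a fully collapsed swarm) all pairs are assigned the interval
    midpoint 2.5 so the force stays well-defined.
    """
    pairwise = np.asarray(pairwise, dtype=float)
    n = pairwise.shape[0]
    if n < 2:
        return pairwise
    off = ~np.eye(n, dtype=bool)
    vals = pairwise[off]
    dmin, dmax = vals.min(), vals.max()
    out = np.zeros_like(pairwise)
    if dmax - dmin <= 1e-12 * max(dmax, 1.0):
        out[off] = 2.5
    else:
        out[off] = 1.0 + 3.0 * (pairwise[off] - dmin) / (dmax - dmin)
    return out


def goa_step(state: SwarmState, config: GOAConfig, c: float):
    """One swarm update: step vectors and proposed positions.

    For grasshopper i and dimension d::

        dX[i, d] = c * sum_{j != i} c * (ub - lb)/2 * S(r_ij) * (x_jd - x_id) / r_ij

    with ``r_ij`` the pairwise Euclidean distance normalized into [1, 4] and
    both damping coefficients equal to the same comfort coefficient ``c``.
    The proposed position is ``dX[i] + target_position``, clipped to the box
    bounds.  Returns ``(step_matrix, proposed_positions)``.
    """
    tol = 1e-12 * max(1.0, config.c_max)
    if not (config.c_min - tol <= c <= config.c_max + tol):
        raise ValueError(f"c={c} outside [{config.c_min}, {config.c_max}]")
    pos = np.asarray(state.positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    n, d = pos.shape
    half_span = (config.upper_bound - config.lower_bound) / 2.0
    if n == 1:
        step = np.zeros_like(pos)
    else:
        dist = cdist(pos, pos)
        r = normalize_distances(dist)
        off = ~np.eye(n, dtype=bool)
        coeff = np.zeros_like(r)
        coeff[off] = social_force(r[off], config.f, config.l) / r[off]
        # sum_j coeff_ij * (x_jd - x_id) = (coeff @ pos)_id - rowsum(coeff)_i * x_id
        interaction = coeff @ pos - coeff.sum(axis=1, keepdims=True) * pos
        step = (c * c * half_span) * interaction
    if not np.all(np.isfinite(step)):
        raise FloatingPointError("non-finite step vector")
    proposed = np.clip(step + state.target_position,
                       config.lower_bound, config.upper_bound)
    return step, proposed
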
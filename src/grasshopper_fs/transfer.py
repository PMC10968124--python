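"""Continuous-to-binary transfer machinery.

Two families of static transfer functions (S-shaped sigmoids with a set-rule,
V-shaped symmetric functions with a flip-rule) plus two time-varying
transfers: the sine transfer |sin(x/alpha)| whose scale alpha grows over the
run, and the TVG transfer — a V4-style arctan shape with steepness scale beta
and an additive Gaussian mutation of standard deviation sigma, both shrinking
over the run.  All outputs are probabilities in [0, 1]; the TVG value is
clipped there because the Gaussian term is unbounded.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .config import TransferSchedule

__all__ = [
    "S_VARIANTS",
    "V_VARIANTS",
    "VARIANTS",
    "s_shaped",
    "v_shaped",
    "schedules",
    "sine_probability",
    "binarize_sine",
    "tvg_probability",
    "tvg_flip",
    "binarize_static",
]

_S_FUNCS = {
    "s1": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "s2": lambda x: 1.0 / (1.0 + np.exp(-2.0 * x)),
    "s3": lambda x: 1.0 / (1.0 + np.exp(-x / 2.0)),
    "s4": lambda x: 1.0 / (1.0 + np.exp(-x / 3.0)),
}

_V_FUNCS = {
    "v1": lambda x: np.abs(erf(np.sqrt(np.pi) / 2.0 * x)),
    "v2": lambda x: np.abs(np.tanh(x)),
    "v3": lambda x: np.abs(x / np.sqrt(1.0 + x * x)),
    "v4": lambda x: np.abs(2.0 / np.pi * np.arctan(np.pi / 2.0 * x)),
}

S_VARIANTS = tuple(_S_FUNCS)
V_VARIANTS = tuple(_V_FUNCS)
#: full catalog of transfer variants accepted by the optimizer / CLI
VARIANTS = S_VARIANTS + V_VARIANTS + ("tvg-sine", "tvg")


def _as_finite(x, name="x"):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def s_shaped(variant: str, x):
    """Evaluate an S-shaped (sigmoid) transfer function; result in (0, 1)."""
    try:
        fn = _S_FUNCS[variant.lower()]
    except KeyError:
        raise ValueError(f"unknown S-shaped variant {variant!r}; "
                         f"choose from {S_VARIANTS}") from None
    out = fn(_as_finite(x))
    return float(out) if out.ndim == 0 else out


def v_shaped(variant: str, x):
    """Evaluate a V-shaped (symmetric) transfer function; result in [0, 1)."""
    try:
        fn = _V_FUNCS[variant.lower()]
    except KeyError:
        raise ValueError(f"unknown V-shaped variant {variant!r}; "
                         f"choose from {V_VARIANTS}") from None
    out = fn(_as_finite(x))
    return float(out) if out.ndim == 0 else out


def schedules(iteration: int, schedule: TransferSchedule):
    """Iteration-indexed (alpha, beta, sigma) of the time-varying transfers.

    alpha increases linearly from alpha_min to alpha_max; beta and sigma
    decrease linearly from their maxima to their minima, so the run moves
    from exploration (fast sine oscillation, heavy Gaussian mutation) to
    exploitation (smooth sine, steep V-shape, negligible mutation).
    """
    L = schedule.max_iterations
    if not 0 <= iteration <= L:
        raise ValueError(f"iteration {iteration} outside [0, {L}]")
    t = iteration / L
    # lerp form so the printed endpoints are hit exactly at iterations 0 and L
    alpha = (1.0 - t) * schedule.alpha_min + t * schedule.alpha_max
    beta = (1.0 - t) * schedule.beta_max + t * schedule.beta_min
    sigma = (1.0 - t) * schedule.sigma_max + t * schedule.sigma_min
    return alpha, beta, sigma


def sine_probability(position, alpha: float):
    """|sin(position / alpha)| — the time-varying sine transfer, in [0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = np.abs(np.sin(_as_finite(position, "position") / alpha))
    return float(out) if out.ndim == 0 else out


def binarize_sine(positions, alpha: float, uniform_draws) -> np.ndarray:
    """Set-rule binarization under the sine transfer: bit = 1 iff draw < prob."""
    positions = np.asarray(positions, dtype=float)
    draws = np.asarray(uniform_draws, dtype=float)
    if positions.shape != draws.shape:
        raise ValueError(f"shape mismatch: positions {positions.shape} "
                         f"vs draws {draws.shape}")
    return (draws < sine_probability(positions, alpha)).astype(np.int8)


def tvg_probability(position, beta: float, sigma: float, gaussian_draw):
    """Time-varying Gaussian transfer probability.

    ``|2/pi * arctan(pi/2 * position/beta)| + sigma * gaussian_draw`` clipped
    into [0, 1].  ``gaussian_draw`` is a standard-normal sample, so the added
    term is Gaussian with standard deviation sigma.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    position = _as_finite(position, "position")
    g = np.asarray(gaussian_draw, dtype=float)
    raw = _V_FUNCS["v4"](position / beta) + sigma * g
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def tvg_flip(bits, positions, beta: float, sigma: float,
             uniform_draws, gaussian_draws) -> np.ndarray:
    """Flip-rule binarization under the TVG transfer.

    Each bit is complemented where the uniform draw falls below the TVG
    probability of the corresponding continuous position, otherwise kept.
    """
    bits = np.asarray(bits)
    positions = np.asarray(positions, dtype=float)
    u = np.asarray(uniform_draws, dtype=float)
    g = np.asarray(gaussian_draws, dtype=float)
    if not (bits.shape == positions.shape == u.shape == g.shape):
        raise ValueError("bits, positions and draw vectors must share a shape")
    p = tvg_probability(positions, beta, sigma, g)
    return np.where(u < p, 1 - bits, bits).astype(np.int8)


def binarize_static(probabilities, rule: str, current_bits, uniform_draws) -> np.ndarray:
    """Generic binarization harness for the static S/V baselines.

    ``set`` rule (S-family): bit = 1 iff draw < p.
    ``flip`` rule (V-family): bit complemented iff draw < p.
    """
    p = np.asarray(probabilities, dtype=float)
    u = np.asarray(uniform_draws, dtype=float)
    bits = np.asarray(current_bits)
    if p.shape != u.shape or bits.shape != p.shape:
        raise ValueError("probabilities, bits and draws must share a shape")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if rule == "set":
        return (u < p).astype(np.int8)
    if rule == "flip":
        return np.where(u < p, 1 - bits, bits).astype(np.int8)
    raise ValueError(f"unknown binarization rule {rule!r}; use 'set' or 'flip'")
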
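"""Main loop of the binary grasshopper optimizer.

Each iteration updates the comfort coefficient and the transfer-function
schedules, moves the swarm in the continuous box via the social-force/target
dynamics, converts the continuous positions to bit masks through the selected
transfer variant, repairs empty masks, evaluates the fitness callable on every
mask, and elitistically replaces the target on strict improvement.

Variant dispatch
----------------
``tvg``       : sine set-rule stage followed by the Gaussian V-shaped flip stage
                (the two-stage time-varying binarization).
``tvg-sine``  : the sine set-rule stage alone.
``s1..s4``    : static sigmoid probability of the position, set-rule.
``v1..v4``    : static V-shaped probability of the position, flip-rule against
                the current mask.

Randomness: a single ``numpy.random.Generator`` seeded from ``seed`` drives
initialization and all draws.  Per iteration the draw order is fixed —
uniform array(s) first, then the Gaussian array for the TVG stage — each array
in C (individual-major, dimension-minor) order, so runs replay bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import GOAConfig, TransferSchedule
from .swarm import SwarmState, comfort_coefficient, goa_step
from .transfer import (
    S_VARIANTS,
    V_VARIANTS,
    VARIANTS,
    binarize_sine,
    binarize_static,
    s_shaped,
    schedules,
    tvg_flip,
    v_shaped,
)

__all__ = ["RunResult", "optimize", "repair_mask"]


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    best_mask: np.ndarray        # (D,) bits
    best_fitness: float
    best_error: float            # classification-error component of the fitness
    subset_size: int
    trace: np.ndarray            # (L,) best fitness after each iteration
    seed: int
    evaluations: int

    @property
    def accuracy(self) -> float:
        return 1.0 - self.best_error


def repair_mask(mask: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Ensure at least one selected feature.

    An all-zero mask gets the bit at the dimension of largest absolute
    continuous position set (first index on ties); any other mask is returned
    unchanged.  The wrapper fitness is undefined on the empty subset, so the
    optimizer never evaluates one.
    """
    mask = np.asarray(mask)
    positions = np.asarray(positions, dtype=float)
    if mask.shape != positions.shape:
        raise ValueError("mask and positions must share a shape")
    if mask.any():
        return mask
    repaired = mask.copy()
    repaired[int(np.argmax(np.abs(positions)))] = 1
    return repaired


def _evaluate(problem: Callable, masks: np.ndarray) -> np.ndarray:
    vals = np.array([float(problem(m)) for m in masks])
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise RuntimeError(
            f"fitness returned a non-finite value {vals[bad]} for mask {masks[bad]}")
    return vals


def _binarize(variant: str, positions: np.ndarray, masks: np.ndarray,
              alpha: float, beta: float, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    n, d = positions.shape
    if variant == "tvg":
        bits = binarize_sine(positions, alpha, rng.random((n, d)))
        return tvg_flip(bits, positions, beta, sigma,
                        rng.random((n, d)), rng.standard_normal((n, d)))
    if variant == "tvg-sine":
        return binarize_sine(positions, alpha, rng.random((n, d)))
    if variant in S_VARIANTS:
        return binarize_static(s_shaped(variant, positions), "set",
                               masks, rng.random((n, d)))
    if variant in V_VARIANTS:
        return binarize_static(v_shaped(variant, positions), "flip",
                               masks, rng.random((n, d)))
    raise ValueError(f"unknown transfer variant {variant!r}; choose from {VARIANTS}")


def optimize(problem: Callable[[np.ndarray], float], config: GOAConfig,
             schedule: TransferSchedule | None = None, variant: str = "tvg",
             seed: int = 0) -> RunResult:
    """Run the binary grasshopper optimizer on a fitness callable.

    Parameters
    ----------
    problem
        Callable mapping a length-D bit vector to a finite fitness (lower is
        better).  May expose ``weight_alpha``/``weight_beta`` matching the
        config; the error component of the best fitness is recovered from the
        config weights.
    config
        Swarm constants; ``config.dim`` must equal the problem dimensionality.
    schedule
        Transfer-function schedules; defaults to the standard ranges with
        ``max_iterations`` taken from the config.
    variant
        One of ``tvg``, ``tvg-sine``, ``s1..s4``, ``v1..v4``.
    seed
        Seed of the single random stream driving the run.
    """
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"unknown transfer variant {variant!r}; choose from {VARIANTS}")
    if schedule is None:
        schedule = TransferSchedule(max_iterations=config.max_iterations)
    if schedule.max_iterations != config.max_iterations:
        raise ValueError("schedule and config disagree on max_iterations")

    rng = np.random.default_rng(seed)
    n, d, L = config.population_size, config.dim, config.max_iterations

    positions = rng.uniform(config.lower_bound, config.upper_bound, size=(n, d))
    masks = (positions > 0.5).astype(np.int8)
    masks = np.array([repair_mask(m, p) for m, p in zip(masks, positions)])
    fitness = _evaluate(problem, masks)
    evaluations = n

    best = int(np.argmin(fitness))
    state = SwarmState(
        positions=positions,
        masks=masks,
        fitness=fitness,
        target_position=positions[best].copy(),
        target_mask=masks[best].copy(),
        target_fitness=float(fitness[best]),
    )

    trace = np.empty(L)
    for it in range(1, L + 1):
        c = comfort_coefficient(it, L, config.c_max, config.c_min)
        alpha, beta, sigma = schedules(it, schedule)
        _, state.positions = goa_step(state, config, c)
        state.masks = _binarize(variant, state.positions, state.masks,
                                alpha, beta, sigma, rng)
        state.masks = np.array([repair_mask(m, p)
                                for m, p in zip(state.masks, state.positions)])
        state.fitness = _evaluate(problem, state.masks)
        evaluations += n
        best = int(np.argmin(state.fitness))
        if state.fitness[best] < state.target_fitness:   # strict: ties keep incumbent
            state.target_fitness = float(state.fitness[best])
            state.target_position = state.positions[best].copy()
            state.target_mask = state.masks[best].copy()
        state.iteration = it
        trace[it - 1] = state.target_fitness

    subset_size = int(state.target_mask.sum())
    # invert fitness = wa*error + wb*size/D to report the error component
    if config.weight_alpha > 0:
        best_error = (state.target_fitness
                      - config.weight_beta * subset_size / d) / config.weight_alpha
    else:
        best_error = float("nan")
    return RunResult(
        best_mask=state.target_mask,
        best_fitness=state.target_fitness,
        best_error=best_error,
        subset_size=subset_size,
        trace=trace,
        seed=seed,
        evaluations=evaluations,
    )
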
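"""Configuration dataclasses shared across the optimizer, transfers, and fitness.

All schedules and the swarm update are parameterised here; defaults follow the
standard settings for the binary grasshopper optimizer with time-varying
Gaussian transfer functions (attraction intensity f=0.5, length scale l=1.5,
comfort coefficient decaying from 1 to 1e-5, fitness weights 0.99/0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GOAConfig:
    """Constants of the continuous grasshopper dynamics and the fitness weights.

    Parameters
    ----------
    f, l
        Intensity and length scale of the social-force function
        ``S(r) = f*exp(-r/l) - exp(-r)``.
    c_max, c_min
        Endpoints of the linearly decaying comfort coefficient.
    population_size, max_iterations, dim
        Swarm size N, iteration budget L, and problem dimensionality D.
    lower_bound, upper_bound
        Box bounds of the continuous positions (scalar, applied per dimension).
    weight_alpha, weight_beta
        Fitness weights of the error term and the subset-size ratio;
        must satisfy weight_alpha = 1 - weight_beta.
    """

    population_size: int
    max_iterations: int
    dim: int
    f: float = 0.5
    l: float = 1.5
    c_max: float = 1.0
    c_min: float = 1e-5
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    weight_alpha: float = 0.99
    weight_beta: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.c_min < self.c_max):
            raise ValueError(f"need 0 < c_min < c_max, got ({self.c_min}, {self.c_max})")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not self.upper_bound > self.lower_bound:
            raise ValueError("upper_bound must exceed lower_bound")
        if self.f <= 0 or self.l <= 0:
            raise ValueError("f and l must be positive")
        if abs(self.weight_alpha + self.weight_beta - 1.0) > 1e-12:
            raise ValueError("weight_alpha + weight_beta must equal 1")


@dataclass(frozen=True)
class TransferSchedule:
    """Linear parameter schedules of the time-varying transfer functions.

    ``alpha`` (sine-transfer scale) increases from ``alpha_min`` to
    ``alpha_max`` over the run; ``beta`` (V-shape steepness scale) and
    ``sigma`` (Gaussian mutation standard deviation) decrease from their
    maxima to their minima.  alpha_min defaults to a small positive floor
    (0.05) rather than zero because the sine transfer divides by alpha.
    """

    max_iterations: int
    alpha_min: float = 0.05
    alpha_max: float = 5.0
    beta_min: float = 0.05
    beta_max: float = 10.0
    sigma_min: float = 0.01
    sigma_max: float = 10.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for lo, hi, name in (
            (self.alpha_min, self.alpha_max, "alpha"),
            (self.beta_min, self.beta_max, "beta"),
            (self.sigma_min, self.sigma_max, "sigma"),
        ):
            if not (0.0 < lo < hi):
                raise ValueError(f"need 0 < {name}_min < {name}_max, got ({lo}, {hi})")


@dataclass(frozen=True)
class SplitSpec:
    """How the dataset is split for the wrapper error estimate.

    ``holdout``: stratified train/test split; the classifier error on the
    held-out fraction is the wrapper error (default 80/20).
    ``three-way``: stratified 50/30/20 train/validation/test split; the
    wrapper error during the search is measured on the validation portion,
    the test portion is reserved for final reporting.
    """

    scheme: str = "holdout"
    train_fraction: float = None  # type: ignore[assignment]
    validation_fraction: float = None  # type: ignore[assignment]
    test_fraction: float = None  # type: ignore[assignment]
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout", "three-way"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")
        defaults = {
            "holdout": (0.8, 0.0, 0.2),
            "three-way": (0.5, 0.3, 0.2),
        }[self.scheme]
        object.__setattr__(
            self, "train_fraction",
            defaults[0] if self.train_fraction is None else self.train_fraction)
        object.__setattr__(
            self, "validation_fraction",
            defaults[1] if self.validation_fraction is None else self.validation_fraction)
        object.__setattr__(
            self, "test_fraction",
            defaults[2] if self.test_fraction is None else self.test_fraction)
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.train_fraction <= 0 or self.test_fraction <= 0:
            raise ValueError("train and test fractions must be positive")
        if self.scheme == "three-way" and self.validation_fraction <= 0:
            raise ValueError("three-way scheme needs a positive validation fraction")
        if self.scheme == "holdout" and self.validation_fraction != 0:
            raise ValueError("holdout scheme has no validation fraction")
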
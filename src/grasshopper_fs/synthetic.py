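"""Synthetic classification datasets and an exhaustive feature-subset oracle.

The generator emulates the structure wrapper feature selection assumes: a
small number of class-informative columns (class-conditional Gaussians whose
mean vectors are ``class_separation`` within-class standard deviations apart
in the joint informative subspace, so the informative features are
individually weak but jointly separating), optional redundant columns (noisy
linear mixes of the informative ones), and label-independent Gaussian noise
columns.  Columns are shuffled with a
recorded permutation and the ground-truth informative columns are flagged in
``Dataset.informative_mask``, so recovery can be asserted without external
data.

``exhaustive_best_subset`` enumerates every non-empty mask (guarded to
D <= 16) under exactly the same split handling as the optimizer's wrapper
fitness, providing a global-optimum oracle for small problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SplitSpec
from .fitness import Dataset, FeatureSelectionProblem

__all__ = ["SyntheticSpec", "generate_dataset", "exhaustive_best_subset"]

_MAX_EXHAUSTIVE_DIM = 16


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    ``class_separation`` is the Euclidean distance between class-conditional
    mean vectors in the joint informative subspace, in units of the
    within-class standard deviation.  The separation is spread over the
    informative columns (each contributes ~sep/sqrt(n_informative)), so no
    single column separates the classes on its own and the optimum subset
    needs all of them; separations around 4 make classes well separated but
    not disjoint.
    """

    n_samples: int = 200
    n_informative: int = 3
    n_noise: int = 7
    n_redundant: int = 0
    n_classes: int = 2
    class_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.n_noise < 0 or self.n_redundant < 0:
            raise ValueError("n_noise and n_redundant must be non-negative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 10 * self.n_classes:
            raise ValueError("need at least 10 samples per class")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be positive")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _class_centroids(n_classes: int, n_informative: int, separation: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Class mean vectors in the informative subspace, pairwise ``separation`` apart.

    The classes sit at the vertices of a regular simplex.  Two classes are
    embedded along the equal-weight diagonal so every informative column
    carries the same share of the separation; more classes are embedded with a
    random orthonormal map (weights then vary by column).  If the simplex does
    not fit (n_informative < n_classes - 1) the embedding is a projection and
    pairwise separations shrink below the nominal value.
    """
    if n_classes == 2:
        u = np.ones(n_informative) / np.sqrt(n_informative)
        return np.vstack([-0.5 * separation * u, 0.5 * separation * u])
    # regular simplex with unit pairwise distance, centred at the origin
    v = np.eye(n_classes) / np.sqrt(2.0)
    v -= v.mean(axis=0)
    _, s, vt = np.linalg.svd(v, full_matrices=False)
    simplex = (v @ vt.T)[:, : n_classes - 1]      # (C, C-1), rank C-1
    q, _ = np.linalg.qr(rng.standard_normal((max(n_informative, n_classes - 1),
                                             n_classes - 1)))
    embed = q[:n_informative, :]                  # (n_inf, C-1)
    return separation * simplex @ embed.T


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Draw a dataset according to ``spec`` (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features

    labels = np.arange(n) % spec.n_classes        # balanced classes
    rng.shuffle(labels)

    centroids = _class_centroids(spec.n_classes, spec.n_informative,
                                 spec.class_separation, rng)
    inf = centroids[labels] + rng.standard_normal((n, spec.n_informative))

    blocks = [inf]
    names = [f"inf_{j}" for j in range(spec.n_informative)]
    if spec.n_redundant:
        mix = rng.standard_normal((spec.n_informative, spec.n_redundant))
        red = inf @ mix
        red += 0.1 * red.std(axis=0) * rng.standard_normal((n, spec.n_redundant))
        blocks.append(red)
        names += [f"red_{j}" for j in range(spec.n_redundant)]
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
        names += [f"noise_{j}" for j in range(spec.n_noise)]

    features = np.hstack(blocks)
    informative = np.zeros(d, dtype=np.int8)
    informative[: spec.n_informative] = 1

    perm = rng.permutation(d)                     # recorded via the shuffled names
    return Dataset(
        features=features[:, perm],
        labels=labels,
        feature_names=[names[i] for i in perm],
        informative_mask=informative[perm],
    )


def exhaustive_best_subset(dataset: Dataset, k: int = 5,
                           split: SplitSpec | None = None, seed: int | None = None,
                           weight_beta: float = 0.01):
    """Globally optimal mask by enumerating all 2^D - 1 non-empty subsets.

    Uses the same split/scaling/KNN pipeline as the optimizer's fitness, so
    its result is a true lower bound for any optimizer run sharing the split.
    Mask index m encodes bit d as ``(m >> d) & 1``; ties keep the lowest index.
    Refuses D > 16.
    """
    d = dataset.n_features
    if d > _MAX_EXHAUSTIVE_DIM:
        raise ValueError(f"exhaustive search refused for D={d} > {_MAX_EXHAUSTIVE_DIM}")
    problem = FeatureSelectionProblem(dataset, k=k, split=split, seed=seed,
                                      weight_beta=weight_beta)
    shifts = np.arange(d)
    best_mask, best_fit = None, np.inf
    for m in range(1, 2 ** d):
        mask = (m >> shifts) & 1
        fit = problem(mask)
        if fit < best_fit:                        # strict: ties keep lowest index
            best_mask, best_fit = mask.astype(np.int8), fit
    return best_mask, float(best_fit)
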
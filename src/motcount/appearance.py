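"""Appearance embeddings, per-track feature galleries, and cosine costs.

The tracker consumes unit-norm appearance vectors of a fixed dimension; it
does not care where they come from.  Two providers are bundled:

* :class:`SyntheticEmbedder` — a deterministic generator that draws a fixed
  mean unit vector per identity and perturbs it with Gaussian noise before
  re-normalising.  It lets the full tracking pipeline run, and be tested,
  without any trained network or image data.
* :data:`DENSENET121_PLAN` — a shape-checked architecture description of
  the DenseNet-121 re-identification backbone (dense blocks of 6/12/24/16
  composite layers, each layer concatenating all earlier outputs in its
  block).  A real embedder built on those weights can be registered through
  the same callable contract; which internal layer supplies the re-ID
  vector is left to that implementation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "as_feature",
    "FeatureGallery",
    "cosine_cost",
    "SyntheticEmbedder",
    "DenseNetLayer",
    "DENSENET121_PLAN",
    "validate_densenet_plan",
    "plan_spatial_sizes",
]

INFEASIBLE = 1e5  # sentinel cost for rows/entries that cannot match


def as_feature(vector: Iterable[float], *, atol: float = 1e-6) -> np.ndarray:
    """Validate and return a unit-norm 1-D feature vector."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"feature must be 1-D, got shape {v.shape}")
    n = np.linalg.norm(v)
    if not np.isfinite(n) or abs(n - 1.0) > atol:
        raise ValueError(f"feature must be unit-norm (|v| = {n:.6g})")
    return v


class FeatureGallery:
    """Bounded FIFO of appearance features for one track (oldest evicted)."""

    def __init__(self, budget: int = 100, dim: int | None = None) -> None:
        if budget < 1:
            raise ValueError("gallery budget must be >= 1")
        self.budget = budget
        self.dim = dim
        self._features: deque[np.ndarray] = deque(maxlen=budget)

    def __len__(self) -> int:
        return len(self._features)

    def add(self, feature: np.ndarray) -> None:
        f = as_feature(feature)
        if self.dim is None:
            self.dim = f.shape[0]
        elif f.shape[0] != self.dim:
            raise ValueError(
                f"feature dimension {f.shape[0]} != gallery dimension {self.dim}"
            )
        self._features.append(f)

    def as_matrix(self) -> np.ndarray:
        if not self._features:
            return np.empty((0, self.dim or 0))
        return np.stack(list(self._features))


def cosine_cost(
    galleries: Sequence[FeatureGallery], detections: Sequence[np.ndarray]
) -> np.ndarray:
    """Min-over-gallery cosine distance matrix, shape (tracks, detections).

    Entry (i, j) is ``min_g (1 - <g, d_j>)`` over gallery i; with unit-norm
    vectors this lies in [0, 2].  Rows for empty galleries are set to the
    infeasible sentinel so the assignment step never picks them on
    appearance alone.
    """
    n_t, n_d = len(galleries), len(detections)
    cost = np.full((n_t, n_d), INFEASIBLE)
    if n_d == 0:
        return cost
    D = np.stack([as_feature(d) for d in detections])
    for i, gal in enumerate(galleries):
        G = gal.as_matrix()
        if G.shape[0] == 0:
            continue
        cost[i] = (1.0 - G @ D.T).min(axis=0)
    return cost


class SyntheticEmbedder:
    """Deterministic identity-keyed embedding generator.

    Each identity maps to a fixed unit mean vector; a call with a
    ``sample`` key adds an isotropic Gaussian perturbation whose expected
    *norm* is ``noise_sigma`` (the per-dimension scale is sigma/sqrt(dim))
    and re-normalises.  Distinct identities are therefore nearly orthogonal
    (cosine cost ~ 1) while within-identity cost stays of order sigma^2.
    The same (identity, sample, seed) triple always yields the same vector,
    so simulated runs are exactly reproducible.
    """

    def __init__(self, dim: int = 128, noise_sigma: float = 0.1, seed: int = 0) -> None:
        if dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.dim = dim
        self.noise_sigma = float(noise_sigma)
        self.seed = int(seed)

    def _rng(self, *keys: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([self.seed, *[int(k) for k in keys]]))
        )

    def mean_vector(self, identity: int) -> np.ndarray:
        v = self._rng(identity).standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def embed(self, identity: int, sample: int = 0) -> np.ndarray:
        v = self.mean_vector(identity)
        if self.noise_sigma > 0:
            noise = self._rng(identity, 1 + sample).standard_normal(self.dim)
            v = v + self.noise_sigma * noise / math.sqrt(self.dim)
        return v / np.linalg.norm(v)

    def __call__(self, identity: int, sample: int = 0) -> np.ndarray:
        return self.embed(identity, sample)


# --------------------------------------------------------------------------
# DenseNet-121 architecture plan
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DenseNetLayer:
    """One stage of the backbone: name, operator, spatial stride, output size.

    ``n_composite`` is the number of (1x1 conv, 3x3 conv) composite layers
    in a dense block; each such layer receives the concatenation of every
    earlier output in its block as input.
    """

    name: str
    operator: str
    stride: int
    output_size: int
    n_composite: int = 0


DENSENET121_PLAN: tuple[DenseNetLayer, ...] = (
    DenseNetLayer("convolution", "7x7 conv, stride 2", 2, 112),
    DenseNetLayer("pooling", "3x3 max pool, stride 2", 2, 56),
    DenseNetLayer("dense_block_1", "(1x1 conv, 3x3 conv) x 6", 1, 56, 6),
    DenseNetLayer("transition_1", "1x1 conv + 2x2 average pool, stride 2", 2, 28),
    DenseNetLayer("dense_block_2", "(1x1 conv, 3x3 conv) x 12", 1, 28, 12),
    DenseNetLayer("transition_2", "1x1 conv + 2x2 average pool, stride 2", 2, 14),
    DenseNetLayer("dense_block_3", "(1x1 conv, 3x3 conv) x 24", 1, 14, 24),
    DenseNetLayer("transition_3", "1x1 conv + 2x2 average pool, stride 2", 2, 7),
    DenseNetLayer("dense_block_4", "(1x1 conv, 3x3 conv) x 16", 1, 7, 16),
    DenseNetLayer("classification", "7x7 global pool, 1000-d fully-connected, softmax", 7, 1),
)

DENSE_BLOCK_SIZES = (6, 12, 24, 16)


def plan_spatial_sizes(
    plan: Sequence[DenseNetLayer] = DENSENET121_PLAN, input_size: int = 224
) -> list[int]:
    """Spatial size after each stage, derived purely from the strides."""
    sizes, s = [], input_size
    for layer in plan:
        s = s // layer.stride
        sizes.append(s)
    return sizes


def validate_densenet_plan(
    plan: Sequence[DenseNetLayer] = DENSENET121_PLAN, input_size: int = 224
) -> list[int]:
    """Check the declared output sizes and dense-block composition.

    Returns the distinct downsampling sequence (112, 56, 28, 14, 7, 1 for a
    224 input).  Raises ``ValueError`` on any inconsistency.
    """
    derived = plan_spatial_sizes(plan, input_size)
    for layer, got in zip(plan, derived):
        if got != layer.output_size:
            raise ValueError(
                f"{layer.name}: stride-derived size {got} != declared {layer.output_size}"
            )
    blocks = tuple(l.n_composite for l in plan if l.n_composite > 0)
    if blocks != DENSE_BLOCK_SIZES:
        raise ValueError(f"dense block sizes {blocks} != {DENSE_BLOCK_SIZES}")
    distinct = []
    for s in derived:
        if not distinct or s != distinct[-1]:
            distinct.append(s)
    return distinct
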
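"""Batch-trained Kohonen self-organizing map on a hexagonal grid.

The SOM maps normalized dR1 time-profiles (high-dimensional, one value per
retained frame) onto a small hexagonal lattice of prototype neurons while
preserving input-space topology.  Defaults follow the analysis protocol
this package implements: an 8x8 hexagonal topology, initial neighborhood
radius 3, 100 ordering ("cover") epochs, 250 maximum epochs, batch
training.

Batch epoch: every profile is assigned to its best matching unit (BMU, the
nearest prototype); each prototype is then replaced by the
neighborhood-kernel-weighted mean of all profiles, with a Gaussian kernel
over lattice distance whose width decays linearly from ``initial_radius``
to 1 over the ordering epochs and stays at 1 for the remaining tuning
epochs.  Training stops early once BMU assignments reach a fixed point
after the ordering phase (the batch update is then stationary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, DomainError

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "SOMWeights",
    "HitMap",
    "hex_distances",
    "init_weights",
    "find_bmu",
    "bmu_indices",
    "batch_train",
    "compute_hitmap",
    "quantization_error",
]


@dataclass(frozen=True)
class SOMConfig:
    """SOM topology and training schedule."""

    rows: int = 8
    cols: int = 8
    layout: str = "hexagonal"
    initial_radius: float = 3.0
    ordering_steps: int = 100
    max_epochs: int = 250
    training_mode: str = "batch"
    init: str = "linear"  # "linear" (deterministic, default) or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise DomainError("grid must have at least 2 neurons")
        if self.initial_radius < 1:
            raise DomainError("initial_radius must be >= 1")
        if not 1 <= self.ordering_steps <= self.max_epochs:
            raise DomainError("require 1 <= ordering_steps <= max_epochs")
        if self.layout != "hexagonal":
            raise DomainError("only the hexagonal layout is implemented")
        if self.training_mode != "batch":
            raise DomainError("only batch training is implemented")
        if self.init not in ("linear", "random"):
            raise DomainError("init must be 'linear' or 'random'")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class SOMGrid:
    """Hex-lattice neuron positions and pairwise lattice distances."""

    positions: np.ndarray  # (n_neurons, 2) in lattice units
    distances: np.ndarray  # (n_neurons, n_neurons) Euclidean

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SOMWeights:
    """Trained prototype vectors plus the topology they live on."""

    weights: np.ndarray  # (n_neurons, n_features)
    config: SOMConfig
    grid: SOMGrid

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class HitMap:
    """Per-neuron BMU hit counts, total and per nested-model label."""

    total: np.ndarray      # (n_neurons,) int
    per_label: np.ndarray  # (n_neurons, 3) int, columns = labels 1/2/3

    def __post_init__(self) -> None:
        if not np.array_equal(self.per_label.sum(axis=1), self.total):
            raise DomainError("per-label hits must sum to totals")


def hex_distances(config: SOMConfig) -> SOMGrid:
    """Offset-row hexagonal lattice: odd rows shift by half a cell, rows
    are sqrt(3)/2 apart, so every interior neuron has six neighbors at
    distance exactly 1."""
    rows, cols = config.rows, config.cols
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    pos = np.column_stack([x, y])
    diff = pos[:, None, :] - pos[None, :, :]
    return SOMGrid(positions=pos, distances=np.hypot(diff[..., 0], diff[..., 1]))


def _top2_principal(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, top-2 eigenvalues and eigenvectors of the data covariance."""
    mu = data.mean(axis=0)
    xc = data - mu
    cov = (xc.T @ xc) / max(data.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:2]
    lams = np.clip(evals[order], 0.0, None)
    # eigenvalues at rounding level of the dominant one are exactly rank loss
    lams[lams < 1e-12 * max(lams[0], 1e-300)] = 0.0
    vecs = evecs[:, order].T
    # deterministic sign: largest-magnitude component positive
    for v in vecs:
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v *= -1.0
    return mu, lams, vecs


def init_weights(data: np.ndarray, config: SOMConfig,
                 grid: SOMGrid | None = None) -> SOMWeights:
    """Deterministic linear initialization on the data's principal plane.

    Prototypes are laid out on a regular grid spanning +-2 standard
    deviations along the first two principal directions (the classic
    "linear" SOM init), giving reproducible training without a random
    state.  ``init="random"`` instead draws prototypes uniformly inside
    the per-feature data range using ``config.seed``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DomainError("data must be (n_samples >= 2, n_features)")
    if grid is None:
        grid = hex_distances(config)
    if np.ptp(x, axis=0).max() == 0:
        raise DegenerateInputError("all training profiles are identical")
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        lo, hi = x.min(axis=0), x.max(axis=0)
        w = rng.uniform(lo, hi, size=(config.n_neurons, x.shape[1]))
        return SOMWeights(weights=w, config=config, grid=grid)
    mu, lams, vecs = _top2_principal(x)
    pos = grid.positions

    def unit_span(v: np.ndarray) -> np.ndarray:
        span = np.ptp(v)
        if span == 0:
            return np.zeros_like(v)
        return 2.0 * (v - v.min()) / span - 1.0

    u = unit_span(pos[:, 0])
    s = unit_span(pos[:, 1])
    w = (mu[None, :]
         + np.outer(u, 2.0 * np.sqrt(lams[0]) * vecs[0])
         + np.outer(s, 2.0 * np.sqrt(lams[1]) * vecs[1]))
    return SOMWeights(weights=w, config=config, grid=grid)


def bmu_indices(weights: SOMWeights | np.ndarray, data: np.ndarray) -> np.ndarray:
    """Best-matching-unit index for each row of ``data``; ties break to the
    lowest neuron index (first minimum)."""
    w = weights.weights if isinstance(weights, SOMWeights) else np.asarray(weights)
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(x)):
        raise DomainError("profiles must be finite")
    if x.shape[1] != w.shape[1]:
        raise DomainError(
            f"profile dimension {x.shape[1]} != prototype dimension {w.shape[1]}"
        )
    d2 = (x * x).sum(axis=1)[:, None] - 2.0 * x @ w.T + (w * w).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1)


def find_bmu(weights: SOMWeights, profile: np.ndarray) -> int:
    """BMU of a single profile (exact squared-distance scan)."""
    w = weights.weights
    x = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("profile must be finite")
    if x.shape != (w.shape[1],):
        raise DomainError("profile dimension does not match prototypes")
    d2 = ((w - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def _radius(config: SOMConfig, epoch: int) -> float:
    """Linear decay initial_radius -> 1 across the ordering epochs, then 1."""
    if epoch >= config.ordering_steps - 1:
        return 1.0
    frac = epoch / max(config.ordering_steps - 1, 1)
    return config.initial_radius + frac * (1.0 - config.initial_radius)


def batch_train(data: np.ndarray, config: SOMConfig | None = None) -> SOMWeights:
    """Train the SOM in batch mode.

    Returns after ``config.max_epochs`` epochs, or earlier once the BMU
    assignment stops changing with the neighborhood radius at its final
    value (the batch update is then at a fixed point).
    """
    if config is None:
        config = SOMConfig()
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise DegenerateInputError("training data must be a nonempty 2-D array")
    grid = hex_distances(config)
    som = init_weights(x, config, grid)
    w = som.weights.copy()
    d2grid = grid.distances ** 2
    prev_bmu = None
    for epoch in range(config.max_epochs):
        bmu = bmu_indices(w, x)
        converged = prev_bmu is not None and np.array_equal(bmu, prev_bmu)
        if converged and epoch >= config.ordering_steps:
            break
        prev_bmu = bmu
        sigma = _radius(config, epoch)
        kernel = np.exp(-d2grid / (2.0 * sigma * sigma))
        sums = np.zeros_like(w)
        np.add.at(sums, bmu, x)
        counts = np.bincount(bmu, minlength=config.n_neurons).astype(float)
        numer = kernel @ sums
        denom = kernel @ counts
        update = denom > 0
        w[update] = numer[update] / denom[update, None]
    return SOMWeights(weights=w, config=config, grid=grid)


def compute_hitmap(weights: SOMWeights, data: np.ndarray,
                   labels: np.ndarray) -> HitMap:
    """Count BMU hits per neuron, overall and per nested-model label."""
    x = np.atleast_2d(np.asarray(data, dtype=float))
    lab = np.asarray(labels)
    if lab.shape != (x.shape[0],):
        raise DomainError("labels length must match number of profiles")
    if not np.isin(lab, (1, 2, 3)).all():
        raise DomainError("labels must be in {1, 2, 3}")
    bmu = bmu_indices(weights, x)
    n = weights.grid.n_neurons
    per_label = np.zeros((n, 3), dtype=np.int64)
    for m in (1, 2, 3):
        per_label[:, m - 1] = np.bincount(bmu[lab == m], minlength=n)
    return HitMap(total=per_label.sum(axis=1), per_label=per_label)


def quantization_error(weights: SOMWeights, data: np.ndarray) -> float:
    """Mean Euclidean distance from each profile to its BMU prototype."""
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] == 0:
        raise DegenerateInputError("data is empty")
    bmu = bmu_indices(weights, x)
    return float(np.linalg.norm(x - weights.weights[bmu], axis=1).mean())
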
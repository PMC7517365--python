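"""Clustering-based one-class classifier over multiple dissimilarities.

The target class is modelled by several independently initialized
k-medoids partitions of the target training patterns, computed under a
weighted Euclidean dissimilarity whose (diagonal) weights are learned.
Each cluster carries a decision region bounded by its average radius
delta plus a threshold sigma, and a sigmoid membership that crosses 0.5
exactly at b = delta + sigma / 2.  A query is accepted when it falls
inside the closest cluster of an instance; instances vote by majority,
and the mean membership of the closest cluster provides a soft score.

A genetic algorithm tunes the weights and the per-cluster thresholds on a
validation set containing both target and non-target patterns, trading
classification accuracy against decision-region extension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dissimilarity import DissimilarityStack
from .ga_search import GAConfig, roulette_select

MAX_KMEDOID_ITER = 100


def concatenate_stack(stack: DissimilarityStack) -> tuple[np.ndarray, dict[int, slice]]:
    """Row-wise concatenation of the per-representation dissimilarity
    matrices into one feature matrix, plus the column slice of each view."""
    blocks = []
    slices: dict[int, slice] = {}
    start = 0
    for rep_id in stack.rep_ids:
        m = stack.matrices[rep_id]
        blocks.append(m)
        slices[rep_id] = slice(start, start + m.shape[1])
        start += m.shape[1]
    return np.hstack(blocks), slices


def weighted_dissimilarity(x1, x2, weights) -> float:
    """sqrt((x1 - x2)^T W^T W (x1 - x2)) with W = diag(weights)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    diff = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    if diff.shape != w.shape:
        raise ValueError("weights and patterns must have equal length")
    return float(np.sqrt(np.sum((w * diff) ** 2)))


def _weighted_distance_matrix(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    xw = x * weights[None, :]
    sq = np.sum(xw**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * xw @ xw.T
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class Cluster:
    """Medoid-centred cluster with its decision region and fuzzy membership.

    a = delta controls the sigmoid steepness, b = delta + sigma/2 its
    midpoint, and boundary = delta + sigma bounds the decision region.
    """

    medoid: int
    members: np.ndarray
    delta: float
    sigma: float = 0.0

    @property
    def a(self) -> float:
        return self.delta

    @property
    def b(self) -> float:
        return self.delta + self.sigma / 2.0

    @property
    def boundary(self) -> float:
        return self.delta + self.sigma

    def membership(self, d: float) -> float:
        """Sigmoid membership in (0, 1); degenerates to an indicator at b
        for singleton (a = 0) clusters."""
        if self.a == 0.0:
            return 1.0 if d <= self.b else 0.0
        z = (d - self.b) / self.a
        if z > 500:
            return 0.0
        if z < -500:
            return 1.0
        return 1.0 / (1.0 + math.exp(z))


def _kmedoids_once(
    dist: np.ndarray, k: int, rng: np.random.Generator
) -> list[Cluster]:
    n = dist.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(MAX_KMEDOID_ITER):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    clusters = []
    for c in range(k):
        members = np.nonzero(assign == c)[0]
        if members.size == 0:
            members = np.array([medoids[c]])
        clusters.append(
            Cluster(
                medoid=int(medoids[c]),
                members=members,
                delta=float(dist[members, medoids[c]].mean()),
            )
        )
    return clusters


def fit_clusters(
    targets: np.ndarray,
    k: int,
    n_instances: int = 5,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> list[list[Cluster]]:
    """k-medoids partitions of the target patterns, one per random restart."""
    targets = np.asarray(targets, dtype=float)
    n = targets.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} target patterns")
    if weights is None:
        weights = np.ones(targets.shape[1])
    dist = _weighted_distance_matrix(targets, np.asarray(weights, dtype=float))
    rng = np.random.default_rng(seed)
    return [_kmedoids_once(dist, k, rng) for _ in range(n_instances)]


@dataclass
class OCCModel:
    """Fitted one-class model: target patterns, weights and the voting
    ensemble of clustering instances (default 5, odd to avoid vote ties)."""

    targets: np.ndarray
    weights: np.ndarray
    instances: list[list[Cluster]]
    k: int
    feature_slices: dict[int, slice] | None = None

    def classify_batch(self, xs) -> tuple[np.ndarray, np.ndarray]:
        """(+/-1 labels, soft scores) for a batch of query patterns.

        Per instance, each query is assigned to its closest cluster and
        accepted when its weighted distance does not exceed the cluster
        boundary (the boundary itself counts as inside); instances vote
        by majority and the soft score is the mean membership of the
        closest cluster.
        """
        from scipy.spatial.distance import cdist

        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        n = xs.shape[0]
        votes = np.zeros(n, dtype=int)
        memberships = np.zeros(n)
        xw = xs * self.weights[None, :]
        for clusters in self.instances:
            medoid_coords = self.targets[[c.medoid for c in clusters]] * self.weights[None, :]
            dists = cdist(xw, medoid_coords)
            closest = np.argmin(dists, axis=1)
            d_closest = dists[np.arange(n), closest]
            boundaries = np.array([c.boundary for c in clusters])
            votes += (d_closest <= boundaries[closest]).astype(int)
            memberships += np.array(
                [clusters[c].membership(d) for c, d in zip(closest, d_closest)]
            )
        decisions = np.where(votes * 2 > len(self.instances), 1, -1)
        return decisions, memberships / len(self.instances)

    def classify(self, x) -> tuple[bool, float]:
        """Single-pattern convenience wrapper around classify_batch."""
        decisions, scores = self.classify_batch(np.atleast_2d(x))
        return bool(decisions[0] == 1), float(scores[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "targets": self.targets.tolist(),
                "weights": self.weights.tolist(),
                "k": self.k,
                "instances": [
                    [
                        {
                            "medoid": c.medoid,
                            "members": c.members.tolist(),
                            "delta": c.delta,
                            "sigma": c.sigma,
                        }
                        for c in clusters
                    ]
                    for clusters in self.instances
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OCCModel":
        d = json.loads(text)
        return cls(
            targets=np.asarray(d["targets"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            k=int(d["k"]),
            instances=[
                [
                    Cluster(
                        medoid=int(c["medoid"]),
                        members=np.asarray(c["members"], dtype=int),
                        delta=float(c["delta"]),
                        sigma=float(c["sigma"]),
                    )
                    for c in clusters
                ]
                for clusters in d["instances"]
            ],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "OCCModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# genetic tuning of weights and thresholds


def _build_model(
    targets: np.ndarray,
    weights: np.ndarray,
    sigma_genes: np.ndarray,
    k: int,
    n_instances: int,
    clustering_seed: int,
) -> OCCModel:
    """Cluster under the candidate weights and apply the sigma genes.

    sigma genes live in [0, 1] and are scaled by the mean pairwise weighted
    distance among targets, so thresholds stay comparable across weight
    candidates."""
    instances = fit_clusters(targets, k, n_instances, clustering_seed, weights)
    dist = _weighted_distance_matrix(targets, weights)
    n = dist.shape[0]
    scale = dist.sum() / (n * (n - 1)) if n > 1 else 1.0
    if scale == 0:
        scale = 1.0
    for inst_idx, clusters in enumerate(instances):
        for c_idx, cluster in enumerate(clusters):
            cluster.sigma = float(sigma_genes[inst_idx, c_idx] * scale)
    return OCCModel(targets=targets, weights=weights, instances=instances, k=k)


def tune_occ(
    train_targets: np.ndarray,
    val_x: np.ndarray,
    val_y,
    k: int = 120,
    config: GAConfig | None = None,
    n_instances: int = 5,
    accuracy_weight: float = 0.5,
    feature_slices: dict[int, slice] | None = None,
) -> tuple[OCCModel, list[float]]:
    """Evolve the dissimilarity weights and per-cluster thresholds.

    The objective (maximized on the validation set, which must contain both
    target (+1) and non-target (-1) patterns) is
    accuracy_weight * accuracy - (1 - accuracy_weight) * mean threshold
    extension.  Returns the best model and the per-generation best
    objective values.

    When feature_slices is given (the per-representation column blocks of
    the concatenated dissimilarity vector), one weight gene is evolved per
    block and expanded to the full diagonal, keeping the search space
    independent of the number of prototypes; otherwise every component
    gets its own gene.
    """
    train_targets = np.asarray(train_targets, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    val_y = np.asarray(val_y)
    if set(np.unique(val_y)) != {-1, 1}:
        raise ValueError("validation set must contain both target and non-target patterns")
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    n_features = train_targets.shape[1]
    blocks = list(feature_slices.values()) if feature_slices else None
    n_weight_genes = len(blocks) if blocks else n_features
    n_genes = n_weight_genes + n_instances * k
    clustering_seed = config.seed + 986_243

    def decode(genes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if blocks:
            weights = np.empty(n_features)
            for gene, sl in zip(genes[:n_weight_genes], blocks):
                weights[sl] = gene
        else:
            weights = genes[:n_weight_genes].copy()
        if weights.sum() == 0:
            weights[:] = 1.0
        return weights, genes[n_weight_genes:].reshape(n_instances, k)

    def objective(genes: np.ndarray) -> float:
        weights, sigma_genes = decode(genes)
        model = _build_model(
            train_targets, weights, sigma_genes, k, n_instances, clustering_seed
        )
        pred, _ = model.classify_batch(val_x)
        accuracy = float(np.mean(pred == val_y))
        return accuracy_weight * accuracy - (1 - accuracy_weight) * float(
            sigma_genes.mean()
        )

    population = [rng.random(n_genes) for _ in range(config.population)]
    fitness = np.array([objective(g) for g in population])
    best_per_gen: list[float] = []

    for generation in range(config.generations):
        best_per_gen.append(float(fitness.max()))
        oriented = fitness - fitness.min()  # roulette needs non-negative values
        order = np.argsort(-fitness)
        elites = [population[i] for i in order[: config.elite_count]]
        n_children = config.population - len(elites)
        parents = roulette_select(population, oriented, rng, 2 * n_children)
        frac = max(
            config.sigma_floor,
            config.mutation_sigma0 * (1.0 - generation / config.generations),
        )
        children = []
        for i in range(n_children):
            pa, pb = parents[2 * i], parents[2 * i + 1]
            child = np.where(rng.random(n_genes) < 0.5, pa, pb)
            child = np.clip(child + rng.normal(0, frac, n_genes), 0.0, 1.0)
            children.append(child)
        child_fitness = np.array([objective(g) for g in children])
        population = elites + children
        fitness = np.concatenate([fitness[order[: config.elite_count]], child_fitness])

    best_idx = int(np.argmax(fitness))
    best_per_gen.append(float(fitness[best_idx]))
    weights, sigma_genes = decode(population[best_idx])
    model = _build_model(
        train_targets, weights, sigma_genes, k, n_instances, clustering_seed
    )
    model.feature_slices = dict(feature_slices) if feature_slices else None
    return model, best_per_gen
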
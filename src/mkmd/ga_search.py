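"""Genetic optimisation of the multiple-kernel nu-SVM.

The genome is [nu, beta, gamma, w]: the SVM regularizer, the convex kernel
weights, the RBF shapes and a binary prototype mask over the training
patterns.  Fitness f1 is the normalized informedness on the validation set
(maximized); fitness f2 = omega * (1 - J_bar) + (1 - omega) * mask density
additionally rewards sparse prototype sets (minimized).

Every objective evaluation runs the full pipeline: slice the precomputed
training dissimilarity stacks by the mask, build the convex multiple
kernel, train the nu-SVM, kernelise the validation patterns against the
training prototypes and score the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityStack, PrototypeMask
from .errors import DegenerateInputError, SVMTrainingError, UndefinedMetricError
from .evaluation import ConfusionCounts, informedness
from .kernels import GAMMA_MAX, KernelSpec, TrainedModel, multiple_kernel, predict, train_nu_svm

NU_MIN = 1e-3
GAMMA_MIN = 1e-3
WORST_F1 = 0.0
WORST_F2 = 1.0


def project_simplex(beta: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and renormalize; an all-zero vector falls back to uniform."""
    beta = np.clip(np.asarray(beta, dtype=float), 0.0, 1.0)
    total = beta.sum()
    if total <= 0:
        return np.full(beta.shape, 1.0 / len(beta))
    return beta / total


@dataclass(frozen=True)
class Genome:
    """One GA individual; all fields satisfy their search-space bounds."""

    nu: float
    beta: tuple
    gamma: tuple
    mask: PrototypeMask
    selection_enabled: bool = True

    def __post_init__(self) -> None:
        if not NU_MIN <= self.nu <= 1.0:
            raise ValueError(f"nu out of bounds: {self.nu}")
        beta = np.asarray(self.beta)
        gamma = np.asarray(self.gamma)
        if np.any(beta < 0) or np.any(beta > 1) or abs(beta.sum() - 1) > 1e-9:
            raise ValueError("beta must lie on the simplex")
        if np.any(gamma < GAMMA_MIN) or np.any(gamma > GAMMA_MAX):
            raise ValueError("gamma out of bounds")
        if not self.selection_enabled and self.mask.n_selected != len(self.mask):
            raise ValueError("mask must be all-ones when selection is disabled")

    @property
    def spec(self) -> KernelSpec:
        return KernelSpec(beta=tuple(self.beta), gamma=tuple(self.gamma))


@dataclass(frozen=True)
class GAConfig:
    """Evolution settings: 100 individuals for up to 100 generations with
    10% elitism, roulette-wheel selection, scattered crossover and a
    Gaussian mutation whose spread shrinks linearly over generations."""

    population: int = 100
    generations: int = 100
    elite_fraction: float = 0.10
    mutation_sigma0: float = 0.10  # initial sigma as a fraction of gene range
    sigma_floor: float = 0.01
    mask_flip_prob: float | None = None  # None -> 1 / mask length
    omega: float = 0.5  # f2 only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population <= 0 or self.generations <= 0:
            raise ValueError("population and generations must be positive")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")

    @property
    def elite_count(self) -> int:
        return max(1, round(self.elite_fraction * self.population))


@dataclass
class EvolutionTrace:
    """Per-generation progress of one GA run (raw fitness scale)."""

    best_fitness: list = field(default_factory=list)
    mean_fitness: list = field(default_factory=list)
    seed: int = 0
    fitness_name: str = "f1"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        )


# ---------------------------------------------------------------------------
# objective evaluation


def fit_and_predict(
    genome: Genome,
    train_stack: DissimilarityStack,
    query_stack: DissimilarityStack,
    y_train,
) -> tuple[TrainedModel, np.ndarray, np.ndarray]:
    """Run the full pipeline for one genome; returns (model, labels, scores)."""
    reduced_train = train_stack.reduce(genome.mask)
    reduced_query = query_stack.reduce(genome.mask)
    spec = genome.spec
    k_train = multiple_kernel(reduced_train, reduced_train, spec)
    model = train_nu_svm(k_train, y_train, genome.nu, spec=spec, mask=genome.mask)
    k_query = multiple_kernel(reduced_query, reduced_train, spec)
    labels, scores = predict(model, k_query)
    return model, labels, scores


def evaluate_f1(
    genome: Genome,
    train_stack: DissimilarityStack,
    val_stack: DissimilarityStack,
    y_train,
    y_val,
) -> float:
    """Normalized informedness of the genome's pipeline on the validation
    set; infeasible genomes receive the worst fitness instead of raising."""
    try:
        _, labels, _ = fit_and_predict(genome, train_stack, val_stack, y_train)
        _, j_bar = informedness(ConfusionCounts.from_predictions(y_val, labels))
        return float(j_bar)
    except (SVMTrainingError, DegenerateInputError, UndefinedMetricError):
        return WORST_F1


def evaluate_f2(
    genome: Genome,
    train_stack: DissimilarityStack,
    val_stack: DissimilarityStack,
    y_train,
    y_val,
    omega: float = 0.5,
) -> float:
    """omega * (1 - J_bar) + (1 - omega) * selected-prototype fraction."""
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    density = genome.mask.n_selected / len(genome.mask)
    try:
        _, labels, _ = fit_and_predict(genome, train_stack, val_stack, y_train)
        _, j_bar = informedness(ConfusionCounts.from_predictions(y_val, labels))
    except (SVMTrainingError, DegenerateInputError, UndefinedMetricError):
        return WORST_F2
    return float(omega * (1.0 - j_bar) + (1.0 - omega) * density)


# ---------------------------------------------------------------------------
# genetic operators


def random_genome(
    n_reps: int,
    n_train: int,
    rng: np.random.Generator,
    selection_enabled: bool = True,
) -> Genome:
    """Random individual: uniform nu, Dirichlet beta, log-uniform gamma,
    Bernoulli(0.5) mask bits."""
    if selection_enabled:
        bits = rng.integers(0, 2, size=n_train)
        if bits.sum() == 0:
            bits[rng.integers(n_train)] = 1
        mask = PrototypeMask.from_array(bits)
    else:
        mask = PrototypeMask.all_ones(n_train)
    return Genome(
        nu=float(rng.uniform(NU_MIN, 1.0)),
        beta=tuple(project_simplex(rng.dirichlet(np.ones(n_reps)))),
        gamma=tuple(10.0 ** rng.uniform(np.log10(GAMMA_MIN), np.log10(GAMMA_MAX), n_reps)),
        mask=mask,
        selection_enabled=selection_enabled,
    )


def roulette_select(
    population: list[Genome],
    oriented_fitnesses,
    rng: np.random.Generator,
    n_parents: int,
) -> list[Genome]:
    """Sample parents with probability proportional to (non-negative)
    oriented fitness; all-zero fitness falls back to uniform sampling."""
    f = np.asarray(oriented_fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("oriented fitnesses must be non-negative")
    total = f.sum()
    probs = np.full(len(f), 1.0 / len(f)) if total <= 0 else f / total
    picks = rng.choice(len(population), size=n_parents, p=probs)
    return [population[i] for i in picks]


def scattered_crossover(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> Genome:
    """Each gene independently inherited from a random parent; beta is
    re-projected to the simplex afterwards."""
    take_b = rng.random() < 0.5
    nu = parent_b.nu if take_b else parent_a.nu
    n_reps = len(parent_a.beta)
    beta = np.where(
        rng.random(n_reps) < 0.5, np.asarray(parent_a.beta), np.asarray(parent_b.beta)
    )
    gamma = np.where(
        rng.random(n_reps) < 0.5, np.asarray(parent_a.gamma), np.asarray(parent_b.gamma)
    )
    if parent_a.selection_enabled:
        bits_a = np.asarray(parent_a.mask.bits)
        bits_b = np.asarray(parent_b.mask.bits)
        bits = np.where(rng.random(len(bits_a)) < 0.5, bits_a, bits_b)
        if bits.sum() == 0:
            bits[rng.integers(len(bits))] = 1
        mask = PrototypeMask.from_array(bits)
    else:
        mask = parent_a.mask
    return Genome(
        nu=nu,
        beta=tuple(project_simplex(beta)),
        gamma=tuple(gamma),
        mask=mask,
        selection_enabled=parent_a.selection_enabled,
    )


def mutate(
    genome: Genome,
    generation: int,
    config: GAConfig,
    rng: np.random.Generator,
) -> Genome:
    """Gaussian perturbation of real genes with a linearly shrinking spread,
    clipped back into bounds; mask bits flip independently."""
    frac = max(
        config.sigma_floor,
        config.mutation_sigma0 * (1.0 - generation / config.generations),
    )
    nu = float(np.clip(genome.nu + rng.normal(0, frac * 1.0), NU_MIN, 1.0))
    n_reps = len(genome.beta)
    beta = project_simplex(np.asarray(genome.beta) + rng.normal(0, frac * 1.0, n_reps))
    gamma = np.clip(
        np.asarray(genome.gamma) + rng.normal(0, frac * GAMMA_MAX, n_reps),
        GAMMA_MIN,
        GAMMA_MAX,
    )
    if genome.selection_enabled:
        bits = np.asarray(genome.mask.bits).copy()
        flip_prob = (
            config.mask_flip_prob
            if config.mask_flip_prob is not None
            else 1.0 / len(bits)
        )
        flips = rng.random(len(bits)) < flip_prob
        bits[flips] = 1 - bits[flips]
        if bits.sum() == 0:
            bits[rng.integers(len(bits))] = 1
        mask = PrototypeMask.from_array(bits)
    else:
        mask = genome.mask
    return Genome(
        nu=nu,
        beta=tuple(beta),
        gamma=tuple(gamma),
        mask=mask,
        selection_enabled=genome.selection_enabled,
    )


# ---------------------------------------------------------------------------
# the generational loop


def _orient(fitness: float, fitness_name: str) -> float:
    """Map raw fitness to a maximize-and-non-negative scale for selection."""
    return fitness if fitness_name == "f1" else 1.0 - fitness


def evolve(
    train_stack: DissimilarityStack,
    val_stack: DissimilarityStack,
    y_train,
    y_val,
    config: GAConfig,
    fitness: str = "f1",
    selection_enabled: bool = True,
) -> tuple[Genome, EvolutionTrace]:
    """Elitist generational GA; returns the validation-best genome and the
    per-generation trace.  Fully reproducible from config.seed."""
    if fitness not in {"f1", "f2"}:
        raise ValueError("fitness must be 'f1' or 'f2'")
    rng = np.random.default_rng(config.seed)
    n_reps = len(train_stack.rep_ids)
    n_train = train_stack.shape[1]

    def score(genome: Genome) -> float:
        if fitness == "f1":
            return evaluate_f1(genome, train_stack, val_stack, y_train, y_val)
        return evaluate_f2(genome, train_stack, val_stack, y_train, y_val, config.omega)

    population = [
        random_genome(n_reps, n_train, rng, selection_enabled)
        for _ in range(config.population)
    ]
    raw = np.array([score(g) for g in population])
    trace = EvolutionTrace(seed=config.seed, fitness_name=fitness)

    for generation in range(config.generations):
        oriented = np.array([_orient(f, fitness) for f in raw])
        order = np.argsort(-oriented)
        trace.best_fitness.append(float(raw[order[0]]))
        trace.mean_fitness.append(float(raw.mean()))

        elites = [population[i] for i in order[: config.elite_count]]
        n_children = config.population - len(elites)
        parents = roulette_select(population, oriented, rng, 2 * n_children)
        children = [
            mutate(
                scattered_crossover(parents[2 * i], parents[2 * i + 1], rng),
                generation,
                config,
                rng,
            )
            for i in range(n_children)
        ]
        population = elites + children
        child_raw = np.array([score(g) for g in children])
        raw = np.concatenate([raw[order[: config.elite_count]], child_raw])

    oriented = np.array([_orient(f, fitness) for f in raw])
    best_idx = int(np.argmax(oriented))
    trace.best_fitness.append(float(raw[best_idx]))
    trace.mean_fitness.append(float(raw.mean()))
    return population[best_idx], trace


def evolve_multi_seed(
    train_stack: DissimilarityStack,
    val_stack: DissimilarityStack,
    y_train,
    y_val,
    config: GAConfig,
    fitness: str = "f1",
    selection_enabled: bool = True,
    n_runs: int = 5,
) -> list[tuple[Genome, EvolutionTrace]]:
    """Repeat evolve with seeds config.seed, config.seed+1, ..."""
    return [
        evolve(
            train_stack,
            val_stack,
            y_train,
            y_val,
            replace(config, seed=config.seed + run),
            fitness=fitness,
            selection_enabled=selection_enabled,
        )
        for run in range(n_runs)
    ]
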
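"""Fixed-length numeric descriptors of a contact network.

Eight complementary views of the same graph are computed, so that a
downstream multi-view learner can weigh them against each other:

1. Betti numbers of the clique (flag) complex — topological holes;
2. node-centrality summary statistics;
3. graph energy and Laplacian energy — spectral mass;
4. network cartography — node role fractions over a modularity partition;
5. heat-content invariants — small-time expansion coefficients of the
   normalized-Laplacian heat content;
6. heat-kernel trace sampled on a time grid;
7. protein size (node count);
8. spectral density of the normalized Laplacian, sampled on a fixed grid.

All eight are graph-isomorphism invariants and are emitted as fixed-length
real vectors whose dimensions depend only on the configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError
from .pcn_io import ContactNetwork

N_REPRESENTATIONS = 8

_DEFAULT_CENTRALITIES = ("degree", "closeness", "betweenness", "eigenvector", "clustering")
_DEFAULT_AGGREGATES = ("mean", "std")


@dataclass(frozen=True)
class RepresentationConfig:
    """Free parameters of the descriptor set.

    betti_max_dim: highest homology dimension reported (b0..b_max).
    centrality_measures/aggregates: which node centralities and which
        summary statistics over nodes.
    heat_t_grid: times at which the heat-kernel trace is sampled.
    heat_content_order: number of expansion coefficients q1..q_order.
    density_grid: evaluation points for the spectral density (the
        normalized-Laplacian spectrum lives in [0, 2]).
    density_bandwidth: Gaussian KDE bandwidth; None selects Silverman's
        rule per graph.
    """

    betti_max_dim: int = 1
    centrality_measures: tuple = _DEFAULT_CENTRALITIES
    centrality_aggregates: tuple = _DEFAULT_AGGREGATES
    heat_t_grid: tuple = tuple(np.logspace(-2, 1, 10))
    heat_content_order: int = 5
    density_grid: tuple = tuple(np.linspace(0.0, 2.0, 100))
    density_bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.betti_max_dim < 0:
            raise ConfigurationError("betti_max_dim must be >= 0")
        if self.heat_content_order < 1:
            raise ConfigurationError("heat_content_order must be >= 1")
        for grid, name in ((self.heat_t_grid, "heat_t_grid"), (self.density_grid, "density_grid")):
            if len(grid) == 0 or np.any(np.diff(grid) <= 0):
                raise ConfigurationError(f"{name} must be non-empty and strictly increasing")
        if self.density_bandwidth is not None and self.density_bandwidth <= 0:
            raise ConfigurationError("density_bandwidth must be positive")

    @property
    def dims(self) -> dict[int, int]:
        """Expected vector length per representation id."""
        return {
            1: self.betti_max_dim + 1,
            2: len(self.centrality_measures) * len(self.centrality_aggregates),
            3: 2,
            4: 8,
            5: self.heat_content_order,
            6: len(self.heat_t_grid),
            7: 1,
            8: len(self.density_grid),
        }


@dataclass
class RepresentationSet:
    """The numeric vectors describing one pattern, keyed by view id 1..8."""

    vectors: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.vectors = {
            int(k): np.asarray(v, dtype=float).ravel() for k, v in self.vectors.items()
        }
        for k, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"representation {k} contains non-finite entries")

    @property
    def dims(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.vectors.items()}

    def __getitem__(self, key: int) -> np.ndarray:
        return self.vectors[key]


class ExtractionError(Exception):
    """One or more representations failed; .failures maps view id -> error."""

    def __init__(self, failures: dict[int, Exception]):
        self.failures = failures
        detail = "; ".join(f"X({k}): {e}" for k, e in failures.items())
        super().__init__(f"representation extraction failed for {detail}")


# ---------------------------------------------------------------------------
# X(1): Betti numbers of the clique complex


def _gf2_rank(matrix: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by column-wise elimination."""
    m = matrix.astype(np.uint8).copy()
    if m.size == 0:
        return 0
    n_rows, n_cols = m.shape
    rank = 0
    for col in range(n_cols):
        pivots = np.nonzero(m[rank:, col])[0]
        if pivots.size == 0:
            continue
        pivot = pivots[0] + rank
        m[[rank, pivot]] = m[[pivot, rank]]
        others = np.nonzero(m[:, col])[0]
        others = others[others != rank]
        m[others] ^= m[rank]
        rank += 1
        if rank == n_rows:
            break
    return rank


def _flag_simplices(g: nx.Graph, max_size: int) -> list[list[tuple]]:
    """Simplices (cliques) of the flag complex grouped by dimension 0..max_size-1."""
    by_dim: list[list[tuple]] = [[] for _ in range(max_size)]
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) > max_size:
            break
        by_dim[len(clique) - 1].append(tuple(sorted(clique)))
    for simplices in by_dim:
        simplices.sort()
    return by_dim


def betti_numbers(net: ContactNetwork, max_dim: int = 1) -> np.ndarray:
    """Ranks (b0..b_max_dim) of the homology groups of the clique complex.

    The clique (flag) complex treats every (k+1)-clique of the graph as a
    k-simplex, so e.g. a triangle is filled and contributes no 1-cycle.
    Homology is computed over GF(2) via boundary-matrix ranks.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    g = net.graph()
    by_dim = _flag_simplices(g, max_size=max_dim + 2)
    counts = [len(s) for s in by_dim]

    ranks = [0] * (max_dim + 2)  # ranks[k] = rank of boundary map del_k
    for k in range(1, max_dim + 2):
        if not by_dim[k] or not by_dim[k - 1]:
            continue
        index = {s: i for i, s in enumerate(by_dim[k - 1])}
        boundary = np.zeros((len(by_dim[k - 1]), len(by_dim[k])), dtype=np.uint8)
        for j, simplex in enumerate(by_dim[k]):
            for face in combinations(simplex, k):
                boundary[index[face], j] = 1
        ranks[k] = _gf2_rank(boundary)

    betti = np.empty(max_dim + 1)
    for k in range(max_dim + 1):
        betti[k] = counts[k] - ranks[k] - ranks[k + 1]
    return betti


# ---------------------------------------------------------------------------
# X(2): centrality summary statistics

_CENTRALITY_FUNCS = {
    "degree": nx.degree_centrality,
    "closeness": nx.closeness_centrality,
    "betweenness": lambda g: nx.betweenness_centrality(g, normalized=True),
    "clustering": nx.clustering,
}


def _eigenvector_centrality(g: nx.Graph) -> dict:
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in g}
    return nx.eigenvector_centrality_numpy(g)


_CENTRALITY_FUNCS["eigenvector"] = _eigenvector_centrality

_AGGREGATE_FUNCS = {
    "mean": np.mean,
    "std": np.std,
    "min": np.min,
    "max": np.max,
    "median": np.median,
}


def centrality_profile(
    net: ContactNetwork, cfg: RepresentationConfig | None = None
) -> np.ndarray:
    """Aggregates (default mean, sd) of node centralities, in fixed order."""
    cfg = cfg or RepresentationConfig()
    g = net.graph()
    out: list[float] = []
    for name in cfg.centrality_measures:
        if name not in _CENTRALITY_FUNCS:
            raise ConfigurationError(f"unknown centrality measure {name!r}")
        values = np.array(list(_CENTRALITY_FUNCS[name](g).values()), dtype=float)
        for agg in cfg.centrality_aggregates:
            if agg not in _AGGREGATE_FUNCS:
                raise ConfigurationError(f"unknown aggregate {agg!r}")
            out.append(float(_AGGREGATE_FUNCS[agg](values)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# X(3): graph energies


def graph_energies(net: ContactNetwork) -> np.ndarray:
    """[graph energy, Laplacian energy].

    Graph energy is the sum of absolute adjacency eigenvalues; Laplacian
    energy is sum |mu_i - 2m/n| over combinatorial-Laplacian eigenvalues.
    """
    n = net.node_count
    if net.edge_count == 0:
        return np.zeros(2)
    a = net.adjacency().toarray()
    adj_eigs = np.linalg.eigvalsh(a)
    lap = np.diag(a.sum(axis=1)) - a
    lap_eigs = np.linalg.eigvalsh(lap)
    mean_degree = 2.0 * net.edge_count / n
    return np.array([np.abs(adj_eigs).sum(), np.abs(lap_eigs - mean_degree).sum()])


# ---------------------------------------------------------------------------
# X(4): network cartography

_HUB_Z = 2.5
# Guimera-Amaral participation-coefficient breakpoints
_NONHUB_P = (0.05, 0.62, 0.80)
_HUB_P = (0.30, 0.75)


def _cartography_role(z: float, p: float) -> int:
    """Role index 0..6 (R1..R7) from within-module z-score and participation."""
    if z < _HUB_Z:
        for role, bound in enumerate(_NONHUB_P):
            if p <= bound:
                return role
        return 3
    for role, bound in enumerate(_HUB_P):
        if p <= bound:
            return 4 + role
    return 6


def cartography_profile(net: ContactNetwork) -> np.ndarray:
    """Fractions of nodes in the 7 cartographic roles, plus modularity.

    Modules come from greedy modularity maximization; each node gets a
    within-module degree z-score and a participation coefficient, and the
    classical role taxonomy (ultra-peripheral ... kinless hub) is applied.
    """
    if net.edge_count == 0:
        raise DegenerateInputError("cartography requires at least one edge")
    g = net.graph()
    communities = nx.community.greedy_modularity_communities(g)
    modularity = nx.community.modularity(g, communities)
    module_of = {}
    for idx, members in enumerate(communities):
        for v in members:
            module_of[v] = idx

    # within-module degree per node
    within = {
        v: sum(1 for u in g.neighbors(v) if module_of[u] == module_of[v]) for v in g
    }
    role_counts = np.zeros(7)
    module_stats = {}
    for idx, members in enumerate(communities):
        vals = np.array([within[v] for v in members], dtype=float)
        module_stats[idx] = (vals.mean(), vals.std())
    for v in g:
        mean, sd = module_stats[module_of[v]]
        z = (within[v] - mean) / sd if sd > 0 else 0.0
        k = g.degree(v)
        if k == 0:
            p = 0.0
        else:
            shares = np.zeros(len(communities))
            for u in g.neighbors(v):
                shares[module_of[u]] += 1
            p = 1.0 - float(np.sum((shares / k) ** 2))
        role_counts[_cartography_role(z, p)] += 1
    return np.concatenate([role_counts / net.node_count, [modularity]])


# ---------------------------------------------------------------------------
# X(5), X(6), X(8): normalized-Laplacian spectral descriptors


def _normalized_laplacian_eig(net: ContactNetwork) -> tuple[np.ndarray, np.ndarray]:
    g = net.graph()
    lap = nx.normalized_laplacian_matrix(g, nodelist=range(net.node_count)).toarray()
    return np.linalg.eigh(lap)


def heat_content_invariants(net: ContactNetwork, order: int = 5) -> np.ndarray:
    """Coefficients q1..q_order of the heat-content expansion Q(t) = sum q_m t^m.

    The heat content of the normalized-Laplacian heat kernel is
    Q(t) = sum_k s_k^2 exp(-lambda_k t) with s_k the sum of the k-th
    eigenvector's entries, hence q_m = sum_k s_k^2 (-lambda_k)^m / m!.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    eigvals, eigvecs = _normalized_laplacian_eig(net)
    s2 = eigvecs.sum(axis=0) ** 2
    return np.array(
        [np.sum(s2 * (-eigvals) ** m) / math.factorial(m) for m in range(1, order + 1)]
    )


def heat_content(net: ContactNetwork, t: float) -> float:
    """Exact heat content Q(t) from the spectral decomposition (test oracle)."""
    eigvals, eigvecs = _normalized_laplacian_eig(net)
    s2 = eigvecs.sum(axis=0) ** 2
    return float(np.sum(s2 * np.exp(-eigvals * t)))


def heat_trace(net: ContactNetwork, t_grid) -> np.ndarray:
    """Heat-kernel trace sum_k exp(-lambda_k t) over combinatorial-Laplacian
    eigenvalues, evaluated at each time of the grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if np.any(t_grid < 0):
        raise ValueError("times must be >= 0")
    a = net.adjacency().toarray()
    lap = np.diag(a.sum(axis=1)) - a
    eigvals = np.linalg.eigvalsh(lap)
    return np.exp(-np.outer(t_grid, eigvals)).sum(axis=1)


def protein_size(net: ContactNetwork) -> np.ndarray:
    """Single-entry vector holding the residue count."""
    return np.array([float(net.node_count)])


def spectral_density(
    net: ContactNetwork, grid, bandwidth: float | None = None
) -> np.ndarray:
    """Gaussian KDE of the normalized-Laplacian spectrum at fixed grid points.

    bandwidth=None applies Silverman's rule to the eigenvalue sample, with a
    floor of 0.01 for (near-)degenerate spectra.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    eigvals, _ = _normalized_laplacian_eig(net)
    n = eigvals.size
    if bandwidth is None:
        sd = eigvals.std()
        bandwidth = max(0.9 * sd * n ** (-0.2), 1e-2)
    diffs = (grid[:, None] - eigvals[None, :]) / bandwidth
    return np.exp(-0.5 * diffs**2).sum(axis=1) / (n * bandwidth * math.sqrt(2 * math.pi))


# ---------------------------------------------------------------------------
# the full descriptor set

_EXTRACTORS = {
    1: lambda net, cfg: betti_numbers(net, cfg.betti_max_dim),
    2: lambda net, cfg: centrality_profile(net, cfg),
    3: lambda net, cfg: graph_energies(net),
    4: lambda net, cfg: cartography_profile(net),
    5: lambda net, cfg: heat_content_invariants(net, cfg.heat_content_order),
    6: lambda net, cfg: heat_trace(net, cfg.heat_t_grid),
    7: lambda net, cfg: protein_size(net),
    8: lambda net, cfg: spectral_density(net, cfg.density_grid, cfg.density_bandwidth),
}


def extract_all(
    net: ContactNetwork, cfg: RepresentationConfig | None = None
) -> RepresentationSet:
    """Compute all eight representations; failures are collected per view
    and raised together as an ExtractionError tagged by view id."""
    cfg = cfg or RepresentationConfig()
    vectors: dict[int, np.ndarray] = {}
    failures: dict[int, Exception] = {}
    for rep_id, extractor in _EXTRACTORS.items():
        try:
            vectors[rep_id] = extractor(net, cfg)
        except Exception as exc:  # noqa: BLE001 - isolated per representation
            failures[rep_id] = exc
    if failures:
        raise ExtractionError(failures)
    return RepresentationSet(vectors=vectors)


# ---------------------------------------------------------------------------
# serialization


def write_representations_csv(
    patterns: list[RepresentationSet],
    path: str | Path,
    cfg: RepresentationConfig | None = None,
) -> None:
    """Wide CSV (one row per pattern, columns repI_J) plus a JSON config sidecar."""
    path = Path(path)
    rows = []
    for rs in patterns:
        row = {}
        for rep_id in sorted(rs.vectors):
            for j, value in enumerate(rs.vectors[rep_id]):
                row[f"rep{rep_id}_{j}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if cfg is not None:
        sidecar = {
            "betti_max_dim": cfg.betti_max_dim,
            "centrality_measures": list(cfg.centrality_measures),
            "centrality_aggregates": list(cfg.centrality_aggregates),
            "heat_t_grid": list(cfg.heat_t_grid),
            "heat_content_order": cfg.heat_content_order,
            "density_grid": list(cfg.density_grid),
            "density_bandwidth": cfg.density_bandwidth,
        }
        path.with_suffix(".config.json").write_text(json.dumps(sidecar, indent=2))


def read_representations_csv(path: str | Path) -> list[RepresentationSet]:
    """Inverse of write_representations_csv (configuration sidecar ignored)."""
    df = pd.read_csv(path)
    patterns = []
    for _, row in df.iterrows():
        vectors: dict[int, list[float]] = {}
        for col in df.columns:
            rep_part, _ = col.split("_", 1)
            rep_id = int(rep_part.removeprefix("rep"))
            vectors.setdefault(rep_id, []).append(row[col])
        patterns.append(RepresentationSet({k: np.array(v) for k, v in vectors.items()}))
    return patterns
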
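"""Dissimilarity-space embedding of multi-view patterns.

Each pattern is re-described by its distances to a set of reference
patterns (the training set), one matrix per representation.  A binary
prototype mask can then slice columns, giving the reduced dissimilarity
space in which the kernels operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DegenerateInputError
from .representations import RepresentationSet

DEFAULT_MEASURE = "euclidean"
_KNOWN_MEASURES = {"euclidean", "cityblock", "chebyshev", "cosine", "sqeuclidean"}


@dataclass(frozen=True)
class PrototypeMask:
    """Binary column selector over the training patterns."""

    bits: tuple

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0/1")

    @classmethod
    def all_ones(cls, length: int) -> "PrototypeMask":
        return cls(bits=(1,) * length)

    @classmethod
    def from_array(cls, arr) -> "PrototypeMask":
        return cls(bits=tuple(int(b) for b in arr))

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))

    @property
    def indices(self) -> np.ndarray:
        return np.nonzero(np.asarray(self.bits))[0]

    @property
    def sparsity_percent(self) -> float:
        """Percentage of training patterns retained as prototypes."""
        return 100.0 * self.n_selected / len(self.bits)


@dataclass
class DissimilarityStack:
    """Per-representation dissimilarity matrices sharing row/column counts.

    Rows index query patterns, columns index reference (training) patterns.
    """

    matrices: dict[int, np.ndarray]
    measure_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.matrices.values()}
        if len(shapes) > 1:
            raise ValueError(f"matrices disagree in shape: {shapes}")
        for rep_id, m in self.matrices.items():
            if np.any(m < 0) or not np.all(np.isfinite(m)):
                raise ValueError(f"representation {rep_id}: entries must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.matrices.values())).shape

    @property
    def rep_ids(self) -> list[int]:
        return sorted(self.matrices)

    def reduce(self, mask: PrototypeMask) -> "DissimilarityStack":
        """Column-slice every matrix by the prototype mask."""
        return DissimilarityStack(
            matrices={k: reduce_columns(m, mask) for k, m in self.matrices.items()},
            measure_names=dict(self.measure_names),
        )


def pairwise_dissimilarity(
    queries, references, measure: str = DEFAULT_MEASURE
) -> np.ndarray:
    """Matrix of d(query_i, reference_j) under the named measure."""
    if measure not in _KNOWN_MEASURES:
        raise ConfigurationError(f"unknown dissimilarity measure {measure!r}")
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    r = np.atleast_2d(np.asarray(references, dtype=float))
    if q.shape[1] != r.shape[1]:
        raise ValueError(
            f"dimension mismatch: queries have {q.shape[1]} features, "
            f"references have {r.shape[1]}"
        )
    return cdist(q, r, metric=measure)


def symmetrize(d: np.ndarray) -> np.ndarray:
    """Force symmetry as (D + D^T) / 2."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("symmetrize requires a square matrix")
    return 0.5 * (d + d.T)


def reduce_columns(d: np.ndarray, mask: PrototypeMask) -> np.ndarray:
    """Keep the columns whose mask bit is set, preserving order."""
    d = np.asarray(d)
    if len(mask) != d.shape[1]:
        raise ValueError(f"mask length {len(mask)} != column count {d.shape[1]}")
    if mask.n_selected == 0:
        raise DegenerateInputError("prototype mask selects no columns")
    return d[:, mask.indices]


def _stack_matrix(
    queries: list[RepresentationSet],
    references: list[RepresentationSet],
    rep_id: int,
    measure: str,
    scale: tuple[np.ndarray, np.ndarray] | None,
) -> np.ndarray:
    q = np.vstack([p[rep_id] for p in queries])
    r = np.vstack([p[rep_id] for p in references])
    if scale is not None:
        mean, sd = scale
        q = (q - mean) / sd
        r = (r - mean) / sd
    try:
        return pairwise_dissimilarity(q, r, measure)
    except ValueError as exc:
        raise ValueError(f"representation {rep_id}: {exc}") from exc


def build_stacks(
    train: list[RepresentationSet],
    val: list[RepresentationSet],
    test: list[RepresentationSet],
    measures: dict[int, str] | None = None,
    standardize: bool = False,
) -> tuple[DissimilarityStack, DissimilarityStack, DissimilarityStack]:
    """Train-vs-train (symmetrized), val-vs-train and test-vs-train stacks.

    With standardize=True each representation is z-scored using training
    statistics before distances are taken (off by default).
    """
    rep_ids = sorted(train[0].vectors)
    measures = {**{i: DEFAULT_MEASURE for i in rep_ids}, **(measures or {})}
    out: list[DissimilarityStack] = []
    scales: dict[int, tuple[np.ndarray, np.ndarray] | None] = {}
    for rep_id in rep_ids:
        if standardize:
            x = np.vstack([p[rep_id] for p in train])
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            scales[rep_id] = (x.mean(axis=0), sd)
        else:
            scales[rep_id] = None
    for queries in (train, val, test):
        matrices = {
            rep_id: _stack_matrix(queries, train, rep_id, measures[rep_id], scales[rep_id])
            for rep_id in rep_ids
        }
        if queries is train:
            matrices = {k: symmetrize(m) for k, m in matrices.items()}
        out.append(DissimilarityStack(matrices=matrices, measure_names=dict(measures)))
    return tuple(out)
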
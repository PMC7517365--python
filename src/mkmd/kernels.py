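"""Convex multiple-kernel combination over reduced dissimilarity spaces.

One RBF kernel per representation is computed on the rows of the reduced
dissimilarity matrices (each pattern's coordinates are its distances to the
selected prototypes), and the per-view kernels are blended by a convex
weight vector beta.  A convex combination of Gaussian kernels is itself a
valid Mercer kernel, so the blend can feed a precomputed-kernel nu-SVM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVC

from .dissimilarity import DissimilarityStack, PrototypeMask
from .errors import ConstraintViolationError, InfeasibleNuError, SVMTrainingError

GAMMA_MAX = 100.0
BETA_SUM_TOL = 1e-12
SVM_TOL = 1e-3  # fixed solver tolerance, recorded for determinism
SVM_MAX_ITER = 200_000  # hard cap; keeps pathological duals from stalling a search


@dataclass(frozen=True)
class KernelSpec:
    """Weights and shapes of the per-representation RBF kernels.

    beta lies on the probability simplex; gamma entries are in (0, 100].
    """

    beta: tuple
    gamma: tuple

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if beta.shape != gamma.shape or beta.ndim != 1:
            raise ConstraintViolationError("beta and gamma must be equal-length vectors")
        if np.any(beta < 0) or np.any(beta > 1):
            raise ConstraintViolationError("beta entries must lie in [0, 1]")
        if abs(beta.sum() - 1.0) > BETA_SUM_TOL:
            raise ConstraintViolationError(
                f"beta must sum to 1 (got {beta.sum():.15f})"
            )
        if np.any(gamma <= 0) or np.any(gamma > GAMMA_MAX):
            raise ConstraintViolationError(f"gamma entries must lie in (0, {GAMMA_MAX}]")

    @property
    def n_kernels(self) -> int:
        return len(self.beta)

    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    def gamma_array(self) -> np.ndarray:
        return np.asarray(self.gamma, dtype=float)


@dataclass
class KernelMatrix:
    """Kernel evaluations between query rows and reference columns."""

    values: np.ndarray
    row_ids: list | None = None
    col_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue of a (square, symmetric) kernel matrix."""
        return float(np.linalg.eigvalsh(0.5 * (self.values + self.values.T)).min())


def rbf_from_dissimilarity(rows, cols, gamma: float) -> np.ndarray:
    """RBF kernel exp(-gamma * ||r_j - c_k||^2) between dissimilarity-space rows."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    cols = np.atleast_2d(np.asarray(cols, dtype=float))
    if rows.shape[1] != cols.shape[1]:
        raise ValueError(
            f"dimension mismatch: {rows.shape[1]} vs {cols.shape[1]} prototypes"
        )
    return np.exp(-gamma * cdist(rows, cols, metric="sqeuclidean"))


def combine_kernels(per_rep: list[np.ndarray], spec: KernelSpec) -> KernelMatrix:
    """Convex combination sum_i beta_i K^(i); entries stay in [0, 1]."""
    if len(per_rep) != spec.n_kernels:
        raise ConstraintViolationError(
            f"{len(per_rep)} kernels but spec has {spec.n_kernels} weights"
        )
    shapes = {np.asarray(m).shape for m in per_rep}
    if len(shapes) > 1:
        raise ValueError(f"kernel shape mismatch: {shapes}")
    combined = np.zeros(shapes.pop())
    for weight, k in zip(spec.beta_array(), per_rep):
        combined += weight * np.asarray(k, dtype=float)
    return KernelMatrix(values=combined)


def multiple_kernel(
    stack: DissimilarityStack,
    train_stack_reduced: DissimilarityStack,
    spec: KernelSpec,
) -> KernelMatrix:
    """Multiple kernel between the patterns of `stack` and the training
    patterns, both expressed in the same reduced dissimilarity space."""
    rep_ids = stack.rep_ids
    if len(rep_ids) != spec.n_kernels:
        raise ConstraintViolationError(
            f"stack has {len(rep_ids)} representations, spec {spec.n_kernels}"
        )
    gammas = spec.gamma_array()
    per_rep = [
        rbf_from_dissimilarity(
            stack.matrices[rep_id], train_stack_reduced.matrices[rep_id], gammas[idx]
        )
        for idx, rep_id in enumerate(rep_ids)
    ]
    return combine_kernels(per_rep, spec)


@dataclass
class TrainedModel:
    """A fitted precomputed-kernel nu-SVM plus the genome context it used.

    Prediction depends only on kernel rows against the support patterns:
    score(x) = sum_i alpha_i y_i K(x, sv_i) + b, label = sign(score).
    """

    support_indices: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: np.ndarray
    nu: float
    n_train: int
    spec: KernelSpec | None = None
    mask: PrototypeMask | None = None
    solver_tol: float = SVM_TOL

    @property
    def n_support(self) -> int:
        return len(self.support_indices)

    def decision_scores(self, k_query_vs_train: np.ndarray) -> np.ndarray:
        k = np.asarray(k_query_vs_train, dtype=float)
        if k.shape[1] != self.n_train:
            raise ValueError(
                f"kernel has {k.shape[1]} columns but model was trained on "
                f"{self.n_train} patterns"
            )
        return k[:, self.support_indices] @ self.dual_coef + self.intercept

    def to_json(self) -> str:
        payload = {
            "support_indices": self.support_indices.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "classes": self.classes.tolist(),
            "nu": self.nu,
            "n_train": self.n_train,
            "solver_tol": self.solver_tol,
            "spec": None
            if self.spec is None
            else {"beta": list(self.spec.beta), "gamma": list(self.spec.gamma)},
            "mask": None if self.mask is None else list(self.mask.bits),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            support_indices=np.asarray(d["support_indices"], dtype=int),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            classes=np.asarray(d["classes"]),
            nu=float(d["nu"]),
            n_train=int(d["n_train"]),
            solver_tol=float(d["solver_tol"]),
            spec=None
            if d["spec"] is None
            else KernelSpec(beta=tuple(d["spec"]["beta"]), gamma=tuple(d["spec"]["gamma"])),
            mask=None if d["mask"] is None else PrototypeMask(bits=tuple(d["mask"])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def train_nu_svm(
    k_train: KernelMatrix | np.ndarray,
    labels,
    nu: float,
    spec: KernelSpec | None = None,
    mask: PrototypeMask | None = None,
) -> TrainedModel:
    """Fit a nu-SVM on a precomputed train-vs-train kernel with +/-1 labels.

    Raises InfeasibleNuError when nu exceeds the feasible bound implied by
    the class balance (2 * min(n+, n-) / n).
    """
    if not 0 < nu <= 1:
        raise ValueError(f"nu must lie in (0, 1], got {nu}")
    k = k_train.values if isinstance(k_train, KernelMatrix) else np.asarray(k_train)
    y = np.asarray(labels)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both +1 and -1")
    svc = NuSVC(kernel="precomputed", nu=nu, tol=SVM_TOL, max_iter=SVM_MAX_ITER)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svc.fit(k, y)
    except ValueError as exc:
        if "nu" in str(exc).lower() or "infeasible" in str(exc).lower():
            raise InfeasibleNuError(f"nu={nu} infeasible for this class balance") from exc
        raise SVMTrainingError(f"nu-SVM solver failed: {exc}") from exc
    return TrainedModel(
        support_indices=svc.support_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        classes=svc.classes_.copy(),
        nu=nu,
        n_train=k.shape[0],
        spec=spec,
        mask=mask,
    )


def predict(
    model: TrainedModel, k_query_vs_train: KernelMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard +/-1 labels and real decision scores for query patterns.

    Columns of the query kernel must follow training-pattern order; the
    scores feed ROC construction downstream.
    """
    k = (
        k_query_vs_train.values
        if isinstance(k_query_vs_train, KernelMatrix)
        else np.asarray(k_query_vs_train)
    )
    scores = model.decision_scores(k)
    labels = np.where(scores > 0, model.classes[1], model.classes[0])
    return labels, scores
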
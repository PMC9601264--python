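"""KNN classification and k-Means clustering over CCE vectors.

Desk-scale implementations written from first principles so every step is
inspectable: KNN takes a majority vote among the k nearest training
vectors with fully deterministic tie-breaking, and k-Means runs Lloyd
iterations from a seeded greedy farthest-point initialization, asserting
that inertia never increases.  Both default to Euclidean distance on
normalized vectors and can instead operate in the Mahalanobis geometry of
a fitted :class:`~ccekit.similarity.ReferenceModel` (via a whitening
transform), keeping clustering consistent with reference-based scoring.

``extract_dimensions`` projects a cohort onto a subset of metrics — whole
SoC blocks for qualitative metrics — so single factors can be clustered in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError, SchemaError
from .similarity import ReferenceModel
from .vectors import CCESchema, CCEVector

__all__ = [
    "LabeledCohort",
    "ClusteringResult",
    "knn_classify",
    "kmeans_cluster",
    "extract_dimensions",
]


def _as_matrix(cohort: Sequence[CCEVector] | np.ndarray) -> np.ndarray:
    if isinstance(cohort, np.ndarray):
        X = np.asarray(cohort, dtype=float)
        if X.ndim != 2:
            raise InvalidInputError("cohort array must be 2-d (n_vectors, dimension)")
        return X
    if len(cohort) == 0:
        raise InvalidInputError("empty cohort")
    return np.stack([v.values for v in cohort]).astype(float)


def _whitener(model: ReferenceModel | None, dim: int) -> np.ndarray | None:
    """Cholesky factor W of the precision matrix: ||W^T u|| = Mahalanobis norm."""
    if model is None:
        return None
    P = model.precision
    if P.shape != (dim, dim):
        raise SchemaError(f"reference model dimension {P.shape[0]} != cohort dimension {dim}")
    return np.linalg.cholesky(P)


@dataclass(frozen=True)
class LabeledCohort:
    """Training vectors with one class label each."""

    vectors: tuple[CCEVector, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vectors = tuple(self.vectors)
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", labels)
        if len(vectors) != len(labels):
            raise InvalidInputError(
                f"{len(vectors)} vectors but {len(labels)} labels"
            )
        if len(vectors) == 0:
            raise InvalidInputError("labeled cohort must be non-empty")

    def __len__(self) -> int:
        return len(self.vectors)


def knn_classify(
    query: CCEVector | np.ndarray,
    train: LabeledCohort,
    k: int = 5,
    metric: str = "euclidean",
    model: ReferenceModel | None = None,
) -> str:
    """Majority label among the k nearest training vectors.

    Vote ties break by (1) smaller mean neighbor distance, then (2)
    lexicographically smaller class id, so the output is deterministic.
    """
    if not 1 <= k <= len(train):
        raise ConfigError(f"k={k} out of range [1, {len(train)}]")
    if metric not in ("euclidean", "mahalanobis"):
        raise ConfigError(f"unsupported KNN metric {metric!r}")
    if metric == "mahalanobis" and model is None:
        raise ConfigError("mahalanobis KNN requires a fitted ReferenceModel")
    X = _as_matrix(train.vectors)
    q = np.asarray(query.values if isinstance(query, CCEVector) else query, dtype=float)
    if q.shape != (X.shape[1],):
        raise SchemaError(f"query dimension {q.shape} != training dimension {X.shape[1]}")
    W = _whitener(model if metric == "mahalanobis" else None, X.shape[1])
    diff = X - q
    if W is not None:
        diff = diff @ W
    dists = np.sqrt((diff**2).sum(axis=1))
    order = sorted(range(len(train)), key=lambda i: (dists[i], i))[:k]
    votes: dict[str, list[float]] = {}
    for i in order:
        votes.setdefault(train.labels[i], []).append(float(dists[i]))
    return min(
        votes.items(),
        key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0]),
    )[0]


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of a k-Means run."""

    k: int
    assignments: tuple[int, ...]
    centroids: np.ndarray
    inertia: float
    iterations: int


def _init_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding: random first centre, then repeatedly
    the point farthest from its nearest chosen centre (ties by index)."""
    chosen = [int(rng.integers(len(X)))]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        chosen.append(int(np.argmax(d2)))
    return X[chosen].copy()


def kmeans_cluster(
    cohort: Sequence[CCEVector] | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    model: ReferenceModel | None = None,
) -> ClusteringResult:
    """Lloyd's k-Means with seeded farthest-point initialization.

    Runs to an assignment fixed point or ``max_iter``; inertia (the
    within-cluster sum of squared distances) is checked to be
    non-increasing at every iteration.  Bit-reproducible for a fixed seed.
    When ``model`` is given, clustering happens in its Mahalanobis
    geometry; centroids are reported in the original coordinates.
    """
    X = _as_matrix(cohort)
    n = len(X)
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} out of range [1, {n}]")
    W = _whitener(model, X.shape[1])
    Z = X @ W if W is not None else X
    rng = np.random.default_rng(seed)
    centers = _init_centroids(Z, k, rng)

    prev_inertia = np.inf
    assignments = np.full(n, -1, dtype=int)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), new_assign].sum())
        assert inertia <= prev_inertia + 1e-9, "k-means inertia increased"
        prev_inertia = inertia
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        for j in range(k):
            members = Z[assignments == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                # re-seat an empty cluster on the worst-fitted point
                worst = int(np.argmax(d2[np.arange(n), assignments]))
                centers[j] = Z[worst]

    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignments = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), assignments].sum())
    centroids = np.stack(
        [
            X[assignments == j].mean(axis=0) if np.any(assignments == j) else X[0] * np.nan
            for j in range(k)
        ]
    )
    return ClusteringResult(
        k=k,
        assignments=tuple(int(a) for a in assignments),
        centroids=centroids,
        inertia=inertia,
        iterations=iterations,
    )


def extract_dimensions(
    cohort: Sequence[CCEVector], metric_ids: Sequence[str]
) -> list[CCEVector]:
    """Restrict a cohort to the dimensions of the selected metrics.

    Qualitative metrics keep their whole SoC block.  The sub-schema keeps
    the original schema order, so selecting every metric is the identity.
    """
    if not cohort:
        raise InvalidInputError("empty cohort")
    schema = cohort[0].schema
    known = {m.metric_id for m in schema.metrics}
    unknown = [m for m in metric_ids if m not in known]
    if unknown:
        raise SchemaError(f"unknown metric_id(s) {unknown}; schema has {sorted(known)}")
    keep = set(metric_ids)
    sub_schema = CCESchema(
        tuple(m for m in schema.metrics if m.metric_id in keep),
        include_consensus=schema.include_consensus,
    )
    slices = schema.metric_slices()
    idx = np.concatenate(
        [np.arange(slices[m.metric_id].start, slices[m.metric_id].stop)
         for m in schema.metrics if m.metric_id in keep]
    ).astype(int)
    out = []
    for v in cohort:
        if v.schema != schema:
            raise SchemaError("all vectors in a cohort must share one schema")
        out.append(CCEVector(v.encounter_id, sub_schema, v.values[idx], normalized=v.normalized))
    return out
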
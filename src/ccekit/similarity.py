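"""Reference-based similarity scoring of CCE vectors.

Decision support here is framed as distance from a reference: given a
baseline ("ideal") CCE vector — artificial or an actual best-performing
encounter, both are supported — every encounter in a cohort gets a single
continuous dissimilarity score and a rank.  Four distances are offered:

* Euclidean       sqrt(sum (a_i - b_i)^2)
* cosine          1 - a.b / (|a||b|), the angular dissimilarity in [0, 2]
* Canberra        sum |a_i - b_i| / (|a_i| + |b_i|), sensitive near zero
* Mahalanobis     sqrt((x - y)^T S^-1 (x - y)), with S the cohort
                  covariance, which accounts for correlated dimensions

SoC blocks are strongly correlated by construction (neighbouring ranks of
one profile move together), so the cohort covariance is routinely
near-singular; a small ridge ``S + lambda I`` is applied by default before
inversion.  With S = I the Mahalanobis distance reduces exactly to the
Euclidean one.

Vectors are min-max normalized before scoring unless already normalized,
so all dimensions share the 0-1 coordinate scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import distance as _sdist

from .errors import (
    ConfigError,
    InvalidInputError,
    SchemaError,
    SingularCovarianceError,
    UndefinedAngleError,
)
from .vectors import CCEVector, CohortNormalizer, normalize_cohort

__all__ = [
    "ReferenceModel",
    "DistanceResult",
    "euclidean_distance",
    "cosine_distance",
    "canberra_distance",
    "mahalanobis_distance",
    "rank_encounters",
    "METRIC_NAMES",
]

METRIC_NAMES = ("euclidean", "cosine", "canberra", "mahalanobis")


def _check_dims(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError(f"vectors must be 1-d and of equal length, got {a.shape} vs {b.shape}")
    return a, b


def euclidean_distance(a, b) -> float:
    a, b = _check_dims(a, b)
    return float(_sdist.euclidean(a, b))


def cosine_distance(a, b) -> float:
    a, b = _check_dims(a, b)
    if not a.any() or not b.any():
        raise UndefinedAngleError("cosine distance is undefined for a zero vector")
    return float(_sdist.cosine(a, b))


def canberra_distance(a, b) -> float:
    """Canberra distance; coordinates with a_i = b_i = 0 contribute 0."""
    a, b = _check_dims(a, b)
    return float(_sdist.canberra(a, b))


@dataclass
class ReferenceModel:
    """A reference CCE vector with cohort covariance and normalization state.

    ``reference`` may be an artificial ideal or an empirical encounter.
    ``covariance`` is the population covariance of the (normalized) cohort,
    excluding the reference itself; it feeds the Mahalanobis distance.
    ``ridge`` regularizes a singular covariance as S + lambda I with
    lambda = ridge * trace(S)/dim (set ridge=0 to demand exact
    invertibility).
    """

    reference: CCEVector
    covariance: np.ndarray
    normalizer: CohortNormalizer | None = None
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        S = np.asarray(self.covariance, dtype=float)
        dim = len(self.reference)
        if S.shape != (dim, dim):
            raise SchemaError(f"covariance shape {S.shape} != ({dim}, {dim})")
        if not np.allclose(S, S.T, atol=1e-10):
            raise SchemaError("covariance must be symmetric")
        self.covariance = S
        self._precision: np.ndarray | None = None

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[CCEVector],
        reference: CCEVector,
        normalize: bool = True,
        ridge: float = 1e-6,
    ) -> "ReferenceModel":
        """Fit normalization and covariance on a cohort (reference excluded)."""
        if not cohort:
            raise InvalidInputError("cannot fit a reference model on an empty cohort")
        est = [v for v in cohort if v.encounter_id != reference.encounter_id]
        if not est:
            est = list(cohort)
        normalizer = None
        if normalize:
            normalizer = CohortNormalizer().fit(est)
            est = [normalizer.transform(v) for v in est]
            reference = normalizer.transform(reference)
        X = np.stack([v.values for v in est])
        S = np.cov(X, rowvar=False, bias=True) if len(est) > 1 else np.zeros((X.shape[1],) * 2)
        S = np.atleast_2d(S)
        return cls(reference, S, normalizer=normalizer, ridge=ridge)

    @property
    def precision(self) -> np.ndarray:
        """Inverse of the (possibly ridge-regularized) covariance, cached."""
        if self._precision is None:
            S = self.covariance
            if self.ridge > 0:
                lam = self.ridge * np.trace(S) / S.shape[0]
                if lam == 0:  # zero-trace covariance (degenerate cohort)
                    lam = self.ridge
                S = S + lam * np.eye(S.shape[0])
            try:
                self._precision = np.linalg.inv(S)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    "covariance matrix is singular; enable ridge regularization"
                ) from exc
        return self._precision


def mahalanobis_distance(x, y, model: ReferenceModel) -> float:
    """sqrt((x - y)^T S^-1 (x - y)) under the model's covariance."""
    x, y = _check_dims(np.asarray(x), np.asarray(y))
    d2 = float((x - y) @ model.precision @ (x - y))
    # precision is symmetric PSD up to roundoff; clip tiny negatives
    return float(np.sqrt(max(d2, 0.0)))


@dataclass(frozen=True)
class DistanceResult:
    """Distance of one encounter from the reference, with its cohort rank."""

    encounter_id: str
    metric: str
    distance: float
    rank: int


def rank_encounters(
    cohort: Sequence[CCEVector],
    model: ReferenceModel,
    metric: str = "mahalanobis",
) -> list[DistanceResult]:
    """Score every encounter against the reference and rank ascending.

    Ties break lexicographically by encounter_id, so the ranking is
    deterministic and invariant to cohort input order.
    """
    if metric not in METRIC_NAMES:
        raise ConfigError(f"unknown distance metric {metric!r}; choose from {METRIC_NAMES}")
    if not cohort:
        raise InvalidInputError("cannot rank an empty cohort")
    if model.normalizer is not None:
        cohort = [model.normalizer.transform(v) for v in cohort]
    ref = model.reference.values
    scored: list[tuple[float, str]] = []
    for v in cohort:
        if metric == "euclidean":
            d = euclidean_distance(v.values, ref)
        elif metric == "cosine":
            d = cosine_distance(v.values, ref)
        elif metric == "canberra":
            d = canberra_distance(v.values, ref)
        else:
            d = mahalanobis_distance(v.values, ref, model)
        scored.append((d, v.encounter_id))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [
        DistanceResult(encounter_id=eid, metric=metric, distance=d, rank=i + 1)
        for i, (d, eid) in enumerate(scored)
    ]
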
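"""Critical Clinical Event (CCE) vector assembly, normalization and I/O.

A CCE vector is the per-encounter feature vector that mixes raw
quantitative encounter metrics (consult counts, the LOS/PLOS ratio, a
readmission flag, ...) with qualitative expert ratings that have been made
numeric through the strength-of-consensus transform.  Each qualitative
metric contributes one value per rank of its scale — its SoC profile,
optionally Gompertz- and rank-weighted — so the canonical example schema of
3 quantitative metrics plus 4 qualitative metrics on a 5-point scale yields
a 23-dimensional vector.

Layout is fixed and versioned by the schema: quantitative metrics first,
then qualitative SoC blocks, both in schema order, ranks in ascending
value order.  The schema travels with serialized cohorts as a JSON sidecar
so the layout is never implicit.

Cohorts are min-max normalized per dimension to [0, 1] before distance
scoring; the fitted :class:`CohortNormalizer` is reusable so new encounters
can be scored one at a time against a frozen reference cohort.  Constant
dimensions map to 0.5 and binary 0/1 metrics are passed through untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .likert import RankScale, ResponseSample, consensus, soc_profile
from .weighting import GompertzParams, RankWeights, apply_rank_weights, gompertz_weight

__all__ = [
    "MetricSpec",
    "CCESchema",
    "EncounterRecord",
    "CCEVector",
    "build_vector",
    "CohortNormalizer",
    "normalize_cohort",
    "write_vectors",
    "read_vectors",
    "read_encounters",
    "write_encounters",
    "fig3_schema",
]


@dataclass(frozen=True)
class MetricSpec:
    """One metric of the vector schema.

    ``kind`` is "quantitative" (value copied verbatim) or "qualitative"
    (expanded to a SoC block over ``scale``).  ``binary`` marks 0/1
    quantitative metrics that normalization must leave untouched.
    ``gompertz`` and ``rank_weights``, when set on a qualitative metric,
    apply sample-size and per-rank weighting to its SoC block.
    """

    metric_id: str
    kind: Literal["quantitative", "qualitative"]
    scale: RankScale | None = None
    binary: bool = False
    gompertz: GompertzParams | None = None
    rank_weights: RankWeights | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind == "qualitative":
            if self.scale is None:
                raise SchemaError(f"qualitative metric {self.metric_id!r} needs a scale")
            if self.rank_weights is not None and len(self.rank_weights) != len(self.scale):
                raise SchemaError(
                    f"rank_weights length mismatch for metric {self.metric_id!r}"
                )
        elif self.kind == "quantitative":
            if self.scale is not None:
                raise SchemaError(f"quantitative metric {self.metric_id!r} must not carry a scale")
        else:
            raise SchemaError(f"unknown metric kind {self.kind!r}")

    def to_dict(self) -> dict:
        d: dict = {"metric_id": self.metric_id, "kind": self.kind}
        if self.scale is not None:
            d["scale"] = self.scale.to_dict()
        if self.binary:
            d["binary"] = True
        if self.gompertz is not None:
            d["gompertz"] = {"alpha": self.gompertz.alpha, "beta": self.gompertz.beta}
        if self.rank_weights is not None:
            d["rank_weights"] = list(self.rank_weights.weights)
        if self.description:
            d["description"] = self.description
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricSpec":
        return cls(
            metric_id=d["metric_id"],
            kind=d["kind"],
            scale=RankScale.from_dict(d["scale"]) if "scale" in d else None,
            binary=bool(d.get("binary", False)),
            gompertz=GompertzParams(**d["gompertz"]) if "gompertz" in d else None,
            rank_weights=RankWeights(tuple(d["rank_weights"])) if "rank_weights" in d else None,
            description=d.get("description", ""),
        )


@dataclass(frozen=True)
class CCESchema:
    """Ordered, versioned metric layout of a CCE vector.

    ``include_consensus`` appends a consensus scalar after each qualitative
    SoC block (off by default, preserving the canonical 23-dim layout).
    """

    metrics: tuple[MetricSpec, ...]
    include_consensus: bool = False

    def __post_init__(self) -> None:
        metrics = tuple(self.metrics)
        object.__setattr__(self, "metrics", metrics)
        ids = [m.metric_id for m in metrics]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate metric_id in schema: {ids}")
        if self.dimension < 1:
            raise SchemaError("schema dimension must be >= 1")

    @property
    def quantitative(self) -> tuple[MetricSpec, ...]:
        return tuple(m for m in self.metrics if m.kind == "quantitative")

    @property
    def qualitative(self) -> tuple[MetricSpec, ...]:
        return tuple(m for m in self.metrics if m.kind == "qualitative")

    @property
    def dimension(self) -> int:
        dim = len(self.quantitative)
        for m in self.qualitative:
            dim += len(m.scale)  # type: ignore[arg-type]
            if self.include_consensus:
                dim += 1
        return dim

    @property
    def dimension_names(self) -> tuple[str, ...]:
        """Column names, quantitative metrics first then SoC blocks."""
        names = [m.metric_id for m in self.quantitative]
        for m in self.qualitative:
            names.extend(f"{m.metric_id}__{label}" for label in m.scale.labels)  # type: ignore[union-attr]
            if self.include_consensus:
                names.append(f"{m.metric_id}__Cns")
        return tuple(names)

    def metric_slices(self) -> dict[str, slice]:
        """Map metric_id -> slice of its dimensions in the vector."""
        slices: dict[str, slice] = {}
        pos = 0
        for m in self.quantitative:
            slices[m.metric_id] = slice(pos, pos + 1)
            pos += 1
        for m in self.qualitative:
            width = len(m.scale) + (1 if self.include_consensus else 0)  # type: ignore[arg-type]
            slices[m.metric_id] = slice(pos, pos + width)
            pos += width
        return slices

    def to_dict(self) -> dict:
        return {
            "metrics": [m.to_dict() for m in self.metrics],
            "include_consensus": self.include_consensus,
            "dimension": self.dimension,
            "dimension_names": list(self.dimension_names),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CCESchema":
        return cls(
            tuple(MetricSpec.from_dict(m) for m in d["metrics"]),
            include_consensus=bool(d.get("include_consensus", False)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CCESchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fig3_schema(raters_weighting: GompertzParams | None = None) -> CCESchema:
    """The canonical 23-dimension example schema.

    Three quantitative encounter metrics (consult count, LOS/PLOS ratio,
    readmission flag) and four expert-rated qualitative metrics on the
    5-point importance scale.
    """
    scale = RankScale.linear(5)
    qual = lambda mid, desc: MetricSpec(  # noqa: E731
        mid, "qualitative", scale=scale, gompertz=raters_weighting, description=desc
    )
    return CCESchema(
        (
            MetricSpec("consults", "quantitative", description="number of consults"),
            MetricSpec("los_plos_ratio", "quantitative", description="LOS / prescribed LOS"),
            MetricSpec("readmission", "quantitative", binary=True, description="re-admission flag"),
            qual("imp_consults", "importance of number of consults"),
            qual("imp_los_plos", "importance of LOS/PLOS ratio"),
            qual("imp_readmission", "importance of readmission"),
            qual("patient_experience", "patient experience score"),
        )
    )


@dataclass(frozen=True)
class EncounterRecord:
    """Raw per-encounter inputs: one number per quantitative metric and one
    response sample per qualitative metric."""

    encounter_id: str
    quantitative: dict[str, float] = field(default_factory=dict)
    surveys: dict[str, ResponseSample] = field(default_factory=dict)


@dataclass(frozen=True)
class CCEVector:
    """Ordered numeric vector for one encounter under a fixed schema."""

    encounter_id: str
    schema: CCESchema
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schema.dimension,):
            raise SchemaError(
                f"vector length {values.shape} != schema dimension {self.schema.dimension}"
            )

    def __len__(self) -> int:
        return len(self.values)


def build_vector(record: EncounterRecord, schema: CCESchema) -> CCEVector:
    """Assemble the CCE vector for one encounter.

    Quantitative values are copied verbatim in schema order; each
    qualitative metric is expanded to its (optionally weighted) SoC
    profile in ascending rank order.
    """
    values: list[float] = []
    for m in schema.quantitative:
        if m.metric_id not in record.quantitative:
            raise SchemaError(
                f"encounter {record.encounter_id!r} is missing quantitative metric {m.metric_id!r}"
            )
        v = float(record.quantitative[m.metric_id])
        if m.binary and v not in (0.0, 1.0):
            raise SchemaError(
                f"binary metric {m.metric_id!r} must be 0 or 1, got {v} "
                f"(encounter {record.encounter_id!r})"
            )
        values.append(v)
    for m in schema.qualitative:
        if m.metric_id not in record.surveys:
            raise SchemaError(
                f"encounter {record.encounter_id!r} is missing survey for metric {m.metric_id!r}"
            )
        sample = record.surveys[m.metric_id]
        if sample.scale != m.scale:
            raise SchemaError(
                f"survey scale for metric {m.metric_id!r} does not match the schema scale"
            )
        profile = soc_profile(sample)
        if m.rank_weights is not None:
            profile = apply_rank_weights(profile, m.rank_weights)
        block = profile.as_array()
        if m.gompertz is not None:
            block = block * gompertz_weight(sample.q, m.gompertz)
        values.extend(block.tolist())
        if schema.include_consensus:
            c = consensus(sample)
            if m.gompertz is not None:
                c *= gompertz_weight(sample.q, m.gompertz)
            values.append(c)
    return CCEVector(record.encounter_id, schema, np.asarray(values))


# ---------------------------------------------------------------------------
# normalization


class CohortNormalizer:
    """Per-dimension min-max scaler fitted on a reference cohort.

    Constant dimensions map to 0.5 (they carry no contrast, and 0.5 keeps
    them centered); dimensions of binary metrics are passed through as 0/1.
    The fitted state is frozen so new encounters are scored on the same
    scale as the reference cohort.
    """

    def __init__(self) -> None:
        self.schema: CCESchema | None = None
        self.mins_: np.ndarray | None = None
        self.ranges_: np.ndarray | None = None
        self._passthrough: np.ndarray | None = None

    def fit(self, vectors: Sequence[CCEVector]) -> "CohortNormalizer":
        if not vectors:
            raise SchemaError("cannot fit a normalizer on an empty cohort")
        schema = vectors[0].schema
        if any(v.schema != schema for v in vectors):
            raise SchemaError("all vectors in a cohort must share one schema")
        X = np.stack([v.values for v in vectors])
        self.schema = schema
        self.mins_ = X.min(axis=0)
        self.ranges_ = X.max(axis=0) - self.mins_
        passthrough = np.zeros(schema.dimension, dtype=bool)
        slices = schema.metric_slices()
        for m in schema.quantitative:
            if m.binary:
                passthrough[slices[m.metric_id]] = True
        self._passthrough = passthrough
        return self

    def transform(self, vector: CCEVector) -> CCEVector:
        if self.schema is None:
            raise SchemaError("normalizer is not fitted")
        if vector.schema != self.schema:
            raise SchemaError("vector schema does not match the fitted cohort schema")
        if vector.normalized:
            return vector
        x = vector.values.copy()
        live = ~self._passthrough
        rng = self.ranges_
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (x - self.mins_) / rng
        scaled = np.where(rng > 0, scaled, 0.5)
        x[live] = scaled[live]
        return replace(vector, values=x, normalized=True)

    def fit_transform(self, vectors: Sequence[CCEVector]) -> list[CCEVector]:
        self.fit(vectors)
        return [self.transform(v) for v in vectors]


def normalize_cohort(
    vectors: Sequence[CCEVector], normalizer: CohortNormalizer | None = None
) -> list[CCEVector]:
    """Min-max scale a cohort to [0, 1] per dimension.

    Pass a fitted ``normalizer`` to reuse frozen reference statistics;
    otherwise one is fitted on ``vectors``.  Idempotent: normalizing an
    already-normalized cohort is the identity.
    """
    if normalizer is None:
        if all(v.normalized for v in vectors):
            return list(vectors)
        return CohortNormalizer().fit_transform(list(vectors))
    return [normalizer.transform(v) for v in vectors]


# ---------------------------------------------------------------------------
# serialization


def write_vectors(
    vectors: Sequence[CCEVector], path: str | Path, schema_path: str | Path | None = None
) -> None:
    """Write a cohort as CSV plus a JSON schema sidecar.

    Values are written at full double precision (repr round-trip), so a
    read-back is bit-identical.
    """
    if not vectors:
        raise SchemaError("cannot write an empty cohort")
    schema = vectors[0].schema
    if any(v.schema != schema for v in vectors):
        raise SchemaError("all vectors in a cohort must share one schema")
    path = Path(path)
    frame = pd.DataFrame(
        np.stack([v.values for v in vectors]), columns=list(schema.dimension_names)
    )
    frame.insert(0, "encounter_id", [v.encounter_id for v in vectors])
    frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    # (repr writing plus round_trip parsing keeps doubles bit-identical)
    sidecar = Path(schema_path) if schema_path else path.with_suffix(path.suffix + ".schema.json")
    doc = schema.to_dict()
    doc["normalized"] = all(v.normalized for v in vectors)
    Path(sidecar).write_text(json.dumps(doc, indent=2))


def read_vectors(
    path: str | Path, schema_path: str | Path | None = None
) -> list[CCEVector]:
    """Read a cohort CSV with its JSON schema sidecar; inverse of write_vectors."""
    path = Path(path)
    sidecar = Path(schema_path) if schema_path else path.with_suffix(path.suffix + ".schema.json")
    if not sidecar.exists():
        raise FormatError(f"schema sidecar not found: {sidecar}")
    doc = json.loads(sidecar.read_text())
    schema = CCESchema.from_dict(doc)
    normalized = bool(doc.get("normalized", False))
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["encounter_id", *schema.dimension_names]
    if list(frame.columns) != expected:
        raise FormatError(
            f"cohort CSV header {list(frame.columns)} does not match schema layout {expected}"
        )
    return [
        CCEVector(
            str(row["encounter_id"]),
            schema,
            row[list(schema.dimension_names)].to_numpy(dtype=float),
            normalized=normalized,
        )
        for _, row in frame.iterrows()
    ]


def read_encounters(
    metrics_path: str | Path, surveys_path: str | Path, schema: CCESchema
) -> list[EncounterRecord]:
    """Read raw encounter inputs.

    ``metrics_path``: long CSV ``encounter_id,metric_id,value`` with one row
    per quantitative metric.  ``surveys_path``: wide frequency CSV
    ``encounter_id,metric_id,count_1,...,count_n`` with one row per
    qualitative metric.  Encounter order follows the metrics file.
    """
    metrics = pd.read_csv(metrics_path, float_precision="round_trip")
    if set(metrics.columns) < {"encounter_id", "metric_id", "value"}:
        raise FormatError(
            f"encounter metrics CSV needs columns encounter_id,metric_id,value, got {list(metrics.columns)}"
        )
    surveys = pd.read_csv(surveys_path)
    scale_by_metric = {m.metric_id: m.scale for m in schema.qualitative}
    records: list[EncounterRecord] = []
    survey_groups = dict(tuple(surveys.groupby("encounter_id", sort=False)))
    for eid, group in metrics.groupby("encounter_id", sort=False):
        quantitative = dict(zip(group["metric_id"].astype(str), group["value"].astype(float)))
        enc_surveys: dict[str, ResponseSample] = {}
        sgroup = survey_groups.get(eid)
        if sgroup is not None:
            for _, row in sgroup.iterrows():
                mid = str(row["metric_id"])
                scale = scale_by_metric.get(mid)
                if scale is None:
                    raise SchemaError(f"survey for unknown qualitative metric {mid!r}")
                counts = tuple(int(row[f"count_{i}"]) for i in range(1, len(scale) + 1))
                enc_surveys[mid] = ResponseSample(scale, counts)
        records.append(EncounterRecord(str(eid), quantitative, enc_surveys))
    return records


def write_encounters(
    records: Sequence[EncounterRecord],
    metrics_path: str | Path,
    surveys_path: str | Path,
) -> None:
    """Inverse of read_encounters: emit the long metrics CSV and the wide
    survey frequency CSV."""
    metric_rows = []
    survey_rows = []
    for rec in records:
        for mid, value in rec.quantitative.items():
            metric_rows.append({"encounter_id": rec.encounter_id, "metric_id": mid, "value": value})
        for mid, sample in rec.surveys.items():
            row: dict[str, object] = {"encounter_id": rec.encounter_id, "metric_id": mid}
            for i, c in enumerate(sample.counts, start=1):
                row[f"count_{i}"] = c
            survey_rows.append(row)
    pd.DataFrame(metric_rows).to_csv(
        metrics_path, index=False, float_format=lambda x: repr(float(x))
    )
    pd.DataFrame(survey_rows).to_csv(surveys_path, index=False)
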
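"""Ordinal (Likert) scale types and the entropy-based consensus statistics.

A panel of q raters scores an item on an ordered n-point scale with numeric
rank values x_1 < ... < x_n (e.g. 1 = unimportant ... 5 = very important).
Reducing the responses to rank probabilities p_i, this module computes:

* Shannon entropy  H = -sum p_i log2 p_i  (dispersion in bits),
* consensus        Cns = 1 + sum p_i log2(1 - |x_i - mu| / d_x),
* dissension       1 - Cns,
* strength-of-consensus at a reference rank r,
                   SoC(r) = 1 + sum p_i log2(1 - |x_i - r| / (2 d_x)),

where mu is the probability-weighted mean of the rank values and d_x is the
scale width max(x) - min(x).  Consensus is 1 when the panel is unanimous and
0 for an even split on the two extreme ranks; strength-of-consensus stays in
[0, 1] for every reference rank because the halved denominator bounds the
log argument at 1/2 (0 is attained only when every response sits on the
extreme rank opposite the reference).  Unlike the standard deviation these statistics live on
a fixed 0-1 scale independent of the rank domain, which is what makes them
usable as machine-learning features.

Terms with p_i = 0 contribute exactly zero (no log is evaluated), and the
standard deviation is the population form (divisor q), matching the printed
reference tables these statistics are validated against.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScaleError,
    FormatError,
    InvalidReferenceError,
    InvalidSampleError,
)

__all__ = [
    "RankScale",
    "ResponseSample",
    "ConsensusReport",
    "SoCProfile",
    "sample_mean",
    "sample_std",
    "shannon_entropy",
    "consensus",
    "dissension",
    "strength_of_consensus",
    "soc_profile",
    "consensus_report",
    "read_survey_long",
    "read_survey_wide",
    "report_frame",
    "write_report",
]

#: Default 5-point importance scale: Unimportant, Marginally important,
#: Neutral, Important, Very important.
DEFAULT_LABELS_5 = ("U", "M", "N", "I", "V")


@dataclass(frozen=True)
class RankScale:
    """An ordered n-point ordinal scale.

    Parameters
    ----------
    values
        Strictly increasing numeric rank values, length >= 2.
    labels
        Display labels, one per rank.  Presentation-only metadata; all
        statistics operate on the numeric values.
    """

    values: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        if len(values) < 2:
            raise DegenerateScaleError("a rank scale needs at least 2 ranks")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise DegenerateScaleError(f"rank values must be strictly increasing: {values}")
        labels = tuple(self.labels) if self.labels else tuple(str(int(v)) if float(v).is_integer() else str(v) for v in values)
        if len(labels) != len(values):
            raise DegenerateScaleError("labels must match rank values in length")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def width(self) -> float:
        """Scale width d_x = max(values) - min(values)."""
        return self.values[-1] - self.values[0]

    @classmethod
    def linear(cls, n: int, labels: Sequence[str] | None = None) -> "RankScale":
        """Integer scale 1..n; the classic Likert layout."""
        if labels is None and n == 5:
            labels = DEFAULT_LABELS_5
        return cls(tuple(range(1, n + 1)), tuple(labels) if labels else ())

    def to_dict(self) -> dict:
        return {"values": list(self.values), "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "RankScale":
        return cls(tuple(d["values"]), tuple(d.get("labels") or ()))


@dataclass(frozen=True)
class ResponseSample:
    """Rank-frequency vector for one item from q raters.

    ``counts[i]`` is the number of raters who chose rank ``scale.values[i]``.
    """

    scale: RankScale
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != len(self.scale):
            raise InvalidSampleError(
                f"count vector length {len(counts)} != scale length {len(self.scale)}"
            )
        if any(c < 0 for c in counts):
            raise InvalidSampleError(f"negative count in {counts}")
        if sum(counts) < 1:
            raise InvalidSampleError("empty sample: at least one response required")
        object.__setattr__(self, "counts", counts)

    @property
    def q(self) -> int:
        """Total number of respondents."""
        return sum(self.counts)

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.q

    @classmethod
    def from_responses(cls, scale: RankScale, responses: Iterable[float]) -> "ResponseSample":
        """Reduce a raw list of rank responses to counts immediately."""
        counts = [0] * len(scale)
        index = {v: i for i, v in enumerate(scale.values)}
        for r in responses:
            try:
                counts[index[float(r)]] += 1
            except KeyError:
                raise InvalidSampleError(f"response {r!r} is not on the scale {scale.values}") from None
        return cls(scale, tuple(counts))


@dataclass(frozen=True)
class ConsensusReport:
    """Summary statistics for one response sample."""

    mean: float
    std: float
    entropy: float
    consensus: float
    dissension: float


@dataclass(frozen=True)
class SoCProfile:
    """Strength-of-consensus evaluated at every rank, in scale order.

    This is the qualitative block that enters a CCE vector: one value per
    rank, each in [0, 1].
    """

    scale: RankScale
    soc: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.soc) != len(self.scale):
            raise InvalidSampleError("profile length must equal scale length")
        object.__setattr__(self, "soc", tuple(float(s) for s in self.soc))

    def __len__(self) -> int:
        return len(self.soc)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.soc, dtype=float)


# ---------------------------------------------------------------------------
# statistics


def sample_mean(sample: ResponseSample) -> float:
    """Probability-weighted mean of the rank values, mu = sum p_i x_i."""
    return float(sample.probabilities @ np.asarray(sample.scale.values))


def sample_std(sample: ResponseSample) -> float:
    """Population standard deviation sqrt(sum p_i (x_i - mu)^2)."""
    x = np.asarray(sample.scale.values)
    mu = sample_mean(sample)
    return float(np.sqrt(sample.probabilities @ (x - mu) ** 2))


def shannon_entropy(sample: ResponseSample) -> float:
    """Shannon entropy of the rank distribution in bits; 0*log 0 == 0."""
    p = sample.probabilities
    p = p[p > 0]
    return float(-(p @ np.log2(p))) + 0.0  # avoid -0.0 for degenerate samples


def consensus(sample: ResponseSample) -> float:
    """Agreement of the sample about its mean, in [0, 1].

    Cns = 1 + sum_i p_i log2(1 - |x_i - mu| / d_x).  Unanimity gives 1; an
    even split on the two extreme ranks gives 0.
    """
    scale = sample.scale
    if scale.width <= 0:
        raise DegenerateScaleError("consensus requires a scale of positive width")
    x = np.asarray(scale.values)
    p = sample.probabilities
    mu = sample_mean(sample)
    mask = p > 0
    # |x - mu| can only reach d_x when all mass sits on one extreme, and then
    # mu coincides with it, so the log argument is strictly positive here.
    arg = 1.0 - np.abs(x[mask] - mu) / scale.width
    return float(1.0 + p[mask] @ np.log2(arg))


def dissension(sample: ResponseSample) -> float:
    """Disagreement, the complement 1 - consensus(sample)."""
    return 1.0 - consensus(sample)


def strength_of_consensus(sample: ResponseSample, reference_rank: float) -> float:
    """Consensus about a chosen reference rank r instead of the mean.

    SoC(r) = 1 + sum_i p_i log2(1 - |x_i - r| / (2 d_x)).  The doubled
    denominator keeps the log argument >= 1/2, so the value is always in
    [0, 1]: 1 iff all responses sit on the reference rank, 0 only when all
    responses sit on the extreme rank farthest from it.
    """
    scale = sample.scale
    if float(reference_rank) not in scale.values:
        raise InvalidReferenceError(
            f"reference rank {reference_rank!r} is not on the scale {scale.values}"
        )
    x = np.asarray(scale.values)
    p = sample.probabilities
    mask = p > 0
    arg = 1.0 - np.abs(x[mask] - float(reference_rank)) / (2.0 * scale.width)
    return float(1.0 + p[mask] @ np.log2(arg))


def soc_profile(sample: ResponseSample) -> SoCProfile:
    """Strength-of-consensus at every rank of the scale, in scale order."""
    return SoCProfile(
        sample.scale,
        tuple(strength_of_consensus(sample, r) for r in sample.scale.values),
    )


def consensus_report(sample: ResponseSample) -> ConsensusReport:
    """All scalar statistics for one sample in one pass."""
    c = consensus(sample)
    return ConsensusReport(
        mean=sample_mean(sample),
        std=sample_std(sample),
        entropy=shannon_entropy(sample),
        consensus=c,
        dissension=1.0 - c,
    )


# ---------------------------------------------------------------------------
# survey I/O


def read_survey_long(path: str | Path, scale: RankScale) -> dict[str, ResponseSample]:
    """Read a long-format survey CSV ``rater_id,metric_id,rank``.

    Returns one :class:`ResponseSample` per metric_id, in file order.
    """
    df = pd.read_csv(path)
    required = {"rater_id", "metric_id", "rank"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"long survey CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    samples: dict[str, ResponseSample] = {}
    for metric_id, group in df.groupby("metric_id", sort=False):
        samples[str(metric_id)] = ResponseSample.from_responses(scale, group["rank"])
    return samples


def read_survey_wide(path: str | Path, scale: RankScale) -> dict[str, ResponseSample]:
    """Read a wide frequency CSV ``metric_id,count_1,...,count_n``."""
    df = pd.read_csv(path)
    count_cols = [f"count_{i}" for i in range(1, len(scale) + 1)]
    if "metric_id" not in df.columns or any(c not in df.columns for c in count_cols):
        raise FormatError(
            f"wide survey CSV needs columns ['metric_id'] + {count_cols}, got {list(df.columns)}"
        )
    return {
        str(row["metric_id"]): ResponseSample(scale, tuple(int(row[c]) for c in count_cols))
        for _, row in df.iterrows()
    }


def report_frame(samples: dict[str, ResponseSample]) -> pd.DataFrame:
    """Tabulate mean/std/entropy/consensus/dissension and soc_<label> per metric."""
    rows = []
    for metric_id, sample in samples.items():
        rep = consensus_report(sample)
        row: dict[str, object] = {
            "metric_id": metric_id,
            "mean": rep.mean,
            "std": rep.std,
            "entropy": rep.entropy,
            "consensus": rep.consensus,
            "dissension": rep.dissension,
        }
        for label, value in zip(sample.scale.labels, soc_profile(sample).soc):
            row[f"soc_{label}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(samples: dict[str, ResponseSample], path: str | Path) -> None:
    """Write the consensus report as CSV or JSON depending on the suffix."""
    frame = report_frame(samples)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        frame.to_csv(path, index=False)
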
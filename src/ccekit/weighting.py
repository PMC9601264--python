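"""Sample-size and per-rank weighting of consensus statistics.

Two consensus values computed from 5 raters and from 500 raters carry very
different evidential weight, yet the bare statistics cannot tell them
apart.  The adjustment here multiplies a consensus statistic by a Gompertz
sigmoid of the respondent count q,

    w(q) = exp(-alpha * exp(-beta * q)),

which rises from exp(-alpha) at q = 0 towards 1 as q grows.  With the
default alpha = 0.725 and beta = 0.05 the weight at q = 0 is ~0.484 (about
a 50% penalty) and panels of 100 or more raters are left essentially
unpenalized (w(100) > 0.995).  Alternative shapes are a matter of choosing
alpha and beta; neither is fitted from data.

Independently, a non-negative weight per rank can be applied to a
strength-of-consensus profile to emphasise some ranks over others; weights
are multiplicative with no renormalization, so unit weights are the
identity and zero weights act as selectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError, InvalidQuantityError, SchemaError
from .likert import ResponseSample, SoCProfile, consensus, strength_of_consensus

__all__ = [
    "GompertzParams",
    "RankWeights",
    "gompertz_weight",
    "weighted_soc",
    "weighted_consensus",
    "apply_rank_weights",
]


@dataclass(frozen=True)
class GompertzParams:
    """Shape parameters of the sample-size sigmoid.

    ``alpha`` sets the left asymptote exp(-alpha) (the maximum penalty at
    q = 0); ``beta`` sets the knee/slope (how fast the penalty decays with
    q).  Both must be positive.
    """

    alpha: float = 0.725
    beta: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError(f"alpha and beta must be > 0, got {self.alpha}, {self.beta}")


@dataclass(frozen=True)
class RankWeights:
    """Non-negative multiplicative weight per rank, not all zero."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if any(x < 0 for x in w):
            raise ConfigError(f"rank weights must be >= 0: {w}")
        if not any(x > 0 for x in w):
            raise ConfigError("rank weights must not all be zero")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


def gompertz_weight(q: float, params: GompertzParams = GompertzParams()) -> float:
    """Gompertz sigmoid w(q) = exp(-alpha exp(-beta q)), in (0, 1).

    Strictly increasing in q; equals exp(-alpha) at q = 0 and tends to 1
    as q grows.
    """
    if q < 0:
        raise InvalidQuantityError(f"respondent quantity must be >= 0, got {q}")
    return math.exp(-params.alpha * math.exp(-params.beta * q))


def weighted_soc(
    sample: ResponseSample,
    reference_rank: float,
    params: GompertzParams = GompertzParams(),
) -> float:
    """Strength-of-consensus scaled by the Gompertz weight of the sample's q.

    Always <= the unweighted value since the weight is < 1.
    """
    return strength_of_consensus(sample, reference_rank) * gompertz_weight(sample.q, params)


def weighted_consensus(
    sample: ResponseSample, params: GompertzParams = GompertzParams()
) -> float:
    """Consensus scaled by the Gompertz weight of the sample's q."""
    return consensus(sample) * gompertz_weight(sample.q, params)


def apply_rank_weights(profile: SoCProfile, weights: RankWeights) -> SoCProfile:
    """Element-wise product of a SoC profile with per-rank weights."""
    if len(weights) != len(profile):
        raise SchemaError(
            f"rank-weight length {len(weights)} != profile length {len(profile)}"
        )
    return SoCProfile(
        profile.scale,
        tuple(s * w for s, w in zip(profile.soc, weights.weights)),
    )
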
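"""Consensus-statistic unit tests, including a term-by-term oracle.

The oracle below re-derives consensus and strength-of-consensus with plain
Python loops and math.log2, independently of the vectorized library path.
"""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ccekit as ck
from ccekit.errors import (
    DegenerateScaleError,
    FormatError,
    InvalidReferenceError,
    InvalidSampleError,
)

from conftest import PANELS


# ---------------------------------------------------------------------------
# independent brute-force oracle


def oracle_consensus(values, counts):
    q = sum(counts)
    d = max(values) - min(values)
    mu = sum(c * x for c, x in zip(counts, values)) / q
    total = 0.0
    for c, x in zip(counts, values):
        if c:
            total += (c / q) * math.log2(1.0 - abs(x - mu) / d)
    return 1.0 + total


def oracle_soc(values, counts, r):
    q = sum(counts)
    d = max(values) - min(values)
    total = 0.0
    for c, x in zip(counts, values):
        if c:
            total += (c / q) * math.log2(1.0 - abs(x - r) / (2.0 * d))
    return 1.0 + total


def all_count_vectors(n_ranks, max_q):
    for q in range(1, max_q + 1):
        for cuts in itertools.combinations(range(q + n_ranks - 1), n_ranks - 1):
            counts = []
            prev = -1
            for c in cuts:
                counts.append(c - prev - 1)
                prev = c
            counts.append(q + n_ranks - 2 - prev)
            yield tuple(counts)


# ---------------------------------------------------------------------------
# printed reference panel


@pytest.mark.parametrize("name", list(PANELS))
def test_panel_means_and_population_std(panels, name):
    expected_std = {"V1": 2.000, "V2": 1.414, "V3": 0.775, "V4": 0.000}
    s = panels[name]
    assert round(ck.sample_mean(s), 3) == 3.000
    assert round(ck.sample_std(s), 3) == expected_std[name]


@pytest.mark.parametrize(
    "name, expected_profile",
    [
        ("V1", (0.500, 0.565, 0.585, 0.565, 0.500)),
        ("V2", (0.543, 0.704, 0.757, 0.704, 0.543)),
        ("V3", (0.573, 0.798, 0.884, 0.798, 0.573)),
        ("V4", (0.585, 0.807, 1.000, 0.807, 0.585)),
    ],
)
def test_panel_soc_profiles_to_three_decimals(panels, name, expected_profile):
    profile = ck.soc_profile(panels[name])
    assert tuple(round(v, 3) for v in profile.soc) == expected_profile


def test_consensus_anchor_values(panels):
    # extreme even split -> 0, unanimity -> 1
    assert ck.consensus(panels["V1"]) == pytest.approx(0.0, abs=1e-12)
    assert ck.consensus(panels["V4"]) == pytest.approx(1.0, abs=1e-12)


def test_consensus_hand_derived_bimodal(scale5):
    # counts (0,5,0,5,0): mu = 3, both occupied ranks at distance 1,
    # so Cns = 1 + log2(0.75) = 0.584962...
    s = ck.ResponseSample(scale5, (0, 5, 0, 5, 0))
    assert ck.consensus(s) == pytest.approx(1 + math.log2(0.75), abs=1e-12)
    assert ck.dissension(s) == pytest.approx(-math.log2(0.75), abs=1e-12)


@pytest.mark.parametrize(
    "counts, expected_bits",
    [((2, 2, 2, 2, 2), math.log2(5)), ((0, 0, 10, 0, 0), 0.0), ((5, 0, 0, 0, 5), 1.0)],
)
def test_shannon_entropy_known_distributions(scale5, counts, expected_bits):
    assert ck.shannon_entropy(ck.ResponseSample(scale5, counts)) == pytest.approx(
        expected_bits, abs=1e-12
    )


def test_sample_mean_edge_cases(scale5):
    assert ck.sample_mean(ck.ResponseSample(scale5, (10, 0, 0, 0, 0))) == 1.0
    assert ck.sample_mean(ck.ResponseSample(scale5, (1, 0, 0, 0, 3))) == 4.0


# ---------------------------------------------------------------------------
# contracts and errors


def test_empty_sample_rejected(scale5):
    with pytest.raises(InvalidSampleError):
        ck.ResponseSample(scale5, (0, 0, 0, 0, 0))


def test_reference_off_scale_rejected(panels):
    with pytest.raises(InvalidReferenceError):
        ck.strength_of_consensus(panels["V2"], 2.5)


def test_scale_contracts():
    with pytest.raises(DegenerateScaleError):
        ck.RankScale((1,))
    with pytest.raises(DegenerateScaleError):
        ck.RankScale((1, 1, 2))
    with pytest.raises(DegenerateScaleError):
        ck.RankScale((1, 2, 3), labels=("a", "b"))


def test_raw_responses_reduced_to_counts(scale5):
    s = ck.ResponseSample.from_responses(scale5, [5, 1, 1, 5, 3])
    assert s.counts == (2, 0, 1, 0, 2)
    with pytest.raises(InvalidSampleError):
        ck.ResponseSample.from_responses(scale5, [1, 6])


# ---------------------------------------------------------------------------
# invariants


def test_oracle_equivalence_exhaustive_small_samples(scale5):
    """Library vs brute-force term-by-term evaluation, all q <= 6 samples."""
    values = scale5.values
    for counts in all_count_vectors(5, 6):
        if sum(counts) == 0:
            continue
        s = ck.ResponseSample(scale5, counts)
        assert ck.consensus(s) == pytest.approx(oracle_consensus(values, counts), abs=1e-12)
        for r in values:
            assert ck.strength_of_consensus(s, r) == pytest.approx(
                oracle_soc(values, counts, r), abs=1e-12
            )


counts_strategy = st.lists(st.integers(0, 8), min_size=5, max_size=5).filter(
    lambda c: sum(c) > 0
)


@given(counts=counts_strategy)
@settings(max_examples=200, deadline=None)
def test_consensus_bounds_and_unanimity(counts):
    s = ck.ResponseSample(ck.RankScale.linear(5), tuple(counts))
    c = ck.consensus(s)
    assert -1e-12 <= c <= 1 + 1e-12
    assert (c > 1 - 1e-12) == (max(counts) == sum(counts))
    assert ck.consensus(s) + ck.dissension(s) == pytest.approx(1.0, abs=1e-12)


@given(counts=counts_strategy)
@settings(max_examples=200, deadline=None)
def test_soc_bounds_and_unanimity_at_reference(counts):
    s = ck.ResponseSample(ck.RankScale.linear(5), tuple(counts))
    n = len(counts)
    for i, r in enumerate(s.scale.values):
        soc = ck.strength_of_consensus(s, r)
        assert -1e-12 <= soc <= 1 + 1e-12
        assert (soc > 1 - 1e-12) == (counts[i] == sum(counts))
        # 0 is attained exactly when all mass sits on the opposite extreme
        opposite = n - 1 if i == 0 else (0 if i == n - 1 else None)
        hits_zero = opposite is not None and counts[opposite] == sum(counts)
        assert (soc < 1e-12) == hits_zero


@given(
    counts=counts_strategy,
    a=st.floats(0.1, 10.0, allow_nan=False),
    b=st.floats(-50.0, 50.0, allow_nan=False),
)
@settings(max_examples=100, deadline=None)
def test_affine_rank_relabeling_invariance(counts, a, b):
    """x -> a x + b (a > 0) leaves consensus and SoC profiles unchanged."""
    base = ck.RankScale.linear(5)
    mapped = ck.RankScale(tuple(a * v + b for v in base.values))
    s1 = ck.ResponseSample(base, tuple(counts))
    s2 = ck.ResponseSample(mapped, tuple(counts))
    assert ck.consensus(s1) == pytest.approx(ck.consensus(s2), abs=1e-9)
    for r1, r2 in zip(base.values, mapped.values):
        assert ck.strength_of_consensus(s1, r1) == pytest.approx(
            ck.strength_of_consensus(s2, r2), abs=1e-9
        )


@given(counts=counts_strategy)
@settings(max_examples=100, deadline=None)
def test_symmetric_samples_have_palindromic_profiles(counts):
    sym = tuple(c + r for c, r in zip(counts, reversed(counts)))
    s = ck.ResponseSample(ck.RankScale.linear(5), sym)
    soc = ck.soc_profile(s).soc
    assert soc == pytest.approx(tuple(reversed(soc)), abs=1e-12)


def test_central_soc_orders_panels_by_concentration(panels):
    """More concentration about the mode -> higher SoC at the central rank."""
    central = [ck.strength_of_consensus(panels[n], 3) for n in ("V1", "V2", "V3", "V4")]
    assert central == sorted(central)
    assert len(set(central)) == 4


# ---------------------------------------------------------------------------
# survey I/O


def test_survey_io_long_and_wide_agree(tmp_path, scale5):
    long = tmp_path / "long.csv"
    long.write_text(
        "rater_id,metric_id,rank\n"
        + "\n".join(f"r{i},m1,{v}" for i, v in enumerate([1, 1, 5, 5, 3]))
        + "\n"
        + "\n".join(f"r{i},m2,3" for i in range(4))
    )
    wide = tmp_path / "wide.csv"
    wide.write_text("metric_id,count_1,count_2,count_3,count_4,count_5\nm1,2,0,1,0,2\nm2,0,0,4,0,0\n")
    from_long = ck.likert.read_survey_long(long, scale5)
    from_wide = ck.likert.read_survey_wide(wide, scale5)
    assert from_long.keys() == from_wide.keys()
    for k in from_long:
        assert from_long[k].counts == from_wide[k].counts


def test_report_frame_columns_and_write(tmp_path, panels, scale5):
    frame = ck.likert.report_frame(panels)
    assert list(frame.columns) == [
        "metric_id", "mean", "std", "entropy", "consensus", "dissension",
        "soc_U", "soc_M", "soc_N", "soc_I", "soc_V",
    ]
    out = tmp_path / "report.json"
    ck.likert.write_report(panels, out)
    assert out.exists()
    with pytest.raises(FormatError):
        bad = tmp_path / "bad.csv"
        bad.write_text("metric,count\nx,1\n")
        ck.likert.read_survey_wide(bad, scale5)
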
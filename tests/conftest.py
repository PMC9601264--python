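"""Shared fixtures: the canonical printed example panel and small cohorts."""

import pytest

from ccekit import RankScale, ResponseSample, fig3_schema, generate_cohort, well_separated_scenario


@pytest.fixture(scope="session")
def scale5() -> RankScale:
    return RankScale.linear(5)


#: The four illustrative 10-rater panels on the 1-5 importance scale:
#: an extreme split, uniform spread, a centered hump, and unanimity.
PANELS = {
    "V1": (5, 0, 0, 0, 5),
    "V2": (2, 2, 2, 2, 2),
    "V3": (0, 3, 4, 3, 0),
    "V4": (0, 0, 10, 0, 0),
}


@pytest.fixture(scope="session")
def panels(scale5) -> dict[str, ResponseSample]:
    return {name: ResponseSample(scale5, counts) for name, counts in PANELS.items()}


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-encounter 2-cluster synthetic cohort with its planted labels."""
    scenario = well_separated_scenario(n_encounters=24, k=2, seed=7)
    records, labels = generate_cohort(scenario)
    from ccekit import build_vector

    return [build_vector(r, scenario.schema) for r in records], labels
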
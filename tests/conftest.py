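import pytest

from odmfhir import (
    GeneratorConfig,
    bp_fixture,
    full_coverage_fixture,
    generate_study,
)


@pytest.fixture(scope="session")
def bp():
    """The blood-pressure worked example: (study, mapping config)."""
    return bp_fixture()


@pytest.fixture(scope="session")
def full_coverage():
    """The fixture exercising every legacy mapping rule."""
    return full_coverage_fixture()


@pytest.fixture(scope="session")
def protocol_meta():
    """A fully populated protocol-metadata mapping for plan building."""
    return {
        "identifier": "CVS-REG-001",
        "externalIdentifier": "SECONDARY-42",
        "title": "Cardiovascular episodes study",
        "officialTitle": "A longitudinal study of cardiovascular episodes",
        "registrationDate": "2016-01-15",
        "authoringBody": "Example Trial Registry",
        "status": "active",
        "sponsors": ["Example Research Org", "Example Foundation"],
        "publicContact": {"name": "Study info desk", "telecom": ["mailto:info@example.org"]},
        "investigator": "Dr Example",
        "description": "Cardiovascular episodes in adults",
        "dateFirstEnrolment": "2016-02-01",
        "sampleSize": 120,
        "goals": [
            {"outcome": "Blood pressure control", "metric": "mean systolic BP", "timepoint": "12 weeks"},
            {"outcome": "Event-free survival", "metric": "time to first episode", "timepoint": "12 months"},
        ],
        "note": "synthetic protocol metadata",
    }


def small_study(seed: int, **overrides):
    """A compact seeded study for sweep tests (16 leaves by default)."""
    params = dict(
        seed=seed,
        n_subjects=2,
        n_events=2,
        n_forms_per_event=1,
        n_groups_per_form=2,
        n_items_per_group=2,
    )
    params.update(overrides)
    return generate_study(GeneratorConfig(**params))
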
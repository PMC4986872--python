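from __future__ import annotations

import pytest

from mitonterm.calling import StabilityTable
from mitonterm.filtering import run_filters
from mitonterm.fixtures import FixtureBundle, load_fixtures
from mitonterm.io import map_peptides


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    """The transcribed substrate-table fixtures."""
    return load_fixtures()


@pytest.fixture(scope="session")
def fixture_stability() -> StabilityTable:
    """N-end-rule table used for the published-table runs (M, C unstable)."""
    return StabilityTable().with_unstable("MC")


@pytest.fixture(scope="session")
def icp55_retained(bundle):
    """Mapped + curated ICP55-comparison peptides from the fixtures."""
    mapped, excluded = map_peptides(bundle.peptides["icp55"], bundle.proteins)
    assert not excluded
    _, retained, _ = run_filters(mapped, bundle.localization, bundle.proteins)
    return retained


@pytest.fixture(scope="session")
def oct1_retained(bundle):
    """Mapped + curated OCT1-comparison peptides from the fixtures."""
    peps = bundle.peptides["oct1_1"] + bundle.peptides["oct1_2"]
    mapped, excluded = map_peptides(peps, bundle.proteins)
    assert not excluded
    _, retained, _ = run_filters(mapped, bundle.localization, bundle.proteins)
    return retained
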
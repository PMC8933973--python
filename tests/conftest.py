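import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from pepcover import Peptidome, simulate_community

from _specs import SMALL_SPEC

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_example() -> Peptidome:
    """Six peptides over seven proteins: the desk-scale greedy-cover fixture.

    PEP1 covers {A,D,E,F}; after its selection PEP4 loses every protein and
    the remaining choice is PEP5 {C,G} and then PEP3/PEP6 for B.
    """
    return Peptidome(
        peptides={
            "PEP1": frozenset("ADEF"),
            "PEP2": frozenset("AD"),
            "PEP3": frozenset("BE"),
            "PEP4": frozenset("DF"),
            "PEP5": frozenset("CG"),
            "PEP6": frozenset("B"),
        },
        provenance="target",
        filtered=True,
    )


@pytest.fixture(scope="session")
def small_community():
    """A fast-to-build community shared by read-only tests."""
    return simulate_community(SMALL_SPEC)
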
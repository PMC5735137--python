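import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ttnburden import fixtures
from ttnburden.exact import ExactConfig
from ttnburden.model import TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    return fixtures.brrs_cohort()


@pytest.fixture(scope="session")
def panels():
    return fixtures.reference_panels()


@pytest.fixture(scope="session")
def panels_by_name(panels):
    return {p.name: p for p in panels}


@pytest.fixture(scope="session")
def domain_map():
    return fixtures.ttn_domain_map()


@pytest.fixture(scope="session")
def cfg():
    return ExactConfig()


def random_transcript(rng: np.random.Generator, strand: str) -> TranscriptModel:
    """Random non-overlapping exon model on the requested strand."""
    n_exons = int(rng.integers(1, 7))
    pos = int(rng.integers(1, 500))
    exons = []
    for _ in range(n_exons):
        pos += int(rng.integers(1, 50))  # intron gap
        length = int(rng.integers(1, 60))
        exons.append((pos, pos + length - 1))
        pos += length
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel("RND-1", "chrR", strand, tuple(exons))
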
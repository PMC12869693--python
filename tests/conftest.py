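import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pantag import build_tag_array, random_pangenome, toy_graph  # noqa: E402

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy():
    return toy_graph()


@pytest.fixture(scope="session")
def toy_build(toy):
    index, tags, report = build_tag_array(toy, k=3, degree=8)
    return toy, index, tags, report


@pytest.fixture(scope="session")
def small_pangenome():
    """A bubble-rich single-component pangenome used across suites."""
    return random_pangenome(n_nodes=10, n_haps=3, mut_rate=0.25, seed=42)


@pytest.fixture(scope="session")
def small_build(small_pangenome):
    index, tags, report = build_tag_array(small_pangenome, k=5, degree=8)
    return small_pangenome, index, tags, report
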
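import copy

import pytest

from genodraw.fixtures import demo_spec, generate
from genodraw.seqio import parse_genbank


@pytest.fixture(scope="session")
def demo_set(tmp_path_factory):
    """One generated demo fixture set shared (read-only) by the session."""
    outdir = tmp_path_factory.mktemp("demo_fixtures")
    paths, truth = generate(demo_spec(seed=7), outdir)
    return outdir, paths, truth


@pytest.fixture(scope="session")
def _demo_records_cached(demo_set):
    _, paths, _ = demo_set
    return [rec for p in paths for rec in parse_genbank(p)]


@pytest.fixture
def demo_records(_demo_records_cached):
    """Fresh deep copy per test: tests may flip activity flags etc."""
    return copy.deepcopy(_demo_records_cached)
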
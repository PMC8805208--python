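import io

import pytest

from crosstalk.knowledge_io import (BackgroundNetwork, Pathway,
                                    PathwayCollection, SecretedCatalog)
from crosstalk.synthetic_data import default_spec, generate_bundle


def make_background(edges, nodes=()):
    return BackgroundNetwork.from_edges(edges, nodes=nodes)


def make_pathways(spec_rows):
    """spec_rows: iterable of (id, class, subcategory, excluded, members)."""
    pathways = {}
    for pid, pw_class, subcat, excluded, members in spec_rows:
        pathways[pid] = Pathway(pid, pid, frozenset(members), pw_class,
                                subcat, excluded)
    return PathwayCollection(pathways)


@pytest.fixture
def text():
    return io.StringIO


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(default_spec(rng_seed=0))


@pytest.fixture
def catalog():
    return lambda ids: SecretedCatalog(ids=frozenset(ids))
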
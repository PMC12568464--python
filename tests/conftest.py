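import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _published_tables

from topoentropy import MolecularGraph, build_kekulene


@pytest.fixture(scope="session")
def kekulene():
    return build_kekulene()


@pytest.fixture()
def c6():
    """Benzene skeleton: the 6-cycle."""
    v = list("abcdef")
    return MolecularGraph([(v[i], v[(i + 1) % 6]) for i in range(6)])


@pytest.fixture()
def p3():
    """Path on three vertices."""
    return MolecularGraph([("a", "b"), ("b", "c")])
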
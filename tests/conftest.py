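import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ltrkit import annotate
from ltrkit.synth_fixtures import make_corpus, make_toy_refdb, make_toy_trnas

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def refdb():
    return make_toy_refdb(seed=11)


@pytest.fixture(scope="session")
def trnas():
    return make_toy_trnas(seed=11)


@pytest.fixture(scope="session")
def small_corpus(refdb, trnas):
    """13 elements, one per roster lineage, with truth manifests."""
    elements, manifests, _, _ = make_corpus(13, seed=7, refdb=refdb, trnas=trnas)
    return elements, manifests


@pytest.fixture(scope="session")
def annotated_small(small_corpus, refdb, trnas):
    elements, manifests = small_corpus
    return annotate(elements, refdb, trnas), manifests
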
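import numpy as np
import pytest

from toposim.annotation import GenomeFragment
from toposim.fixtures import annotate_locus_dir, default_locus, synth_epigenome


@pytest.fixture(scope="session")
def locus_dir(tmp_path_factory):
    """Synthetic-locus input stack written once per session."""
    d = tmp_path_factory.mktemp("locus")
    synth_epigenome(default_locus(), d)
    return d


@pytest.fixture(scope="session")
def annotated(locus_dir):
    """(fragment, track) for the default synthetic locus."""
    return annotate_locus_dir(locus_dir)


@pytest.fixture()
def fragment():
    return GenomeFragment("chrT", 0, 600_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
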
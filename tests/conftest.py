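import numpy as np
import pytest

from mitofoot import CleavageProfile, CoverageTrack, GenomeSpec


@pytest.fixture
def genome100():
    return GenomeSpec("chrM", 100)


def make_profile(genome, a=None, t1=None, if_=None, untreated=None, strand="+",
                 genotype="control"):
    """Build a CleavageProfile from dense arrays, defaulting missing tracks to 0."""
    zeros = np.zeros(genome.length)

    def track(v):
        return CoverageTrack(genome, strand, zeros.copy() if v is None else np.asarray(v, float))

    return CleavageProfile(
        a=track(a), t1=track(t1), if_=track(if_), untreated=track(untreated),
        genotype=genotype,
    )


@pytest.fixture
def make_profile_fn():
    return make_profile
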
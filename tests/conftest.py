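import numpy as np
import pytest

from mkconcord.counting import CodonAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pair_alignment():
    """Two-sequence toy with one synonymous third-position difference."""

    def build(n_codons=100, diff_at=0):
        base = "TTT" * n_codons
        other = list(base)
        other[3 * diff_at + 2] = "C"  # TTT -> TTC, Phe/Phe
        return CodonAlignment(names=["a", "b"], sequences=[base, "".join(other)])

    return build
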
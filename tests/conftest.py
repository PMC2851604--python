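import numpy as np
import pytest

from snpdiscover.records import Read


@pytest.fixture
def make_read():
    def _make(bases, id="r0", quals=None, mask=None, **kw):
        if quals is None:
            quals = np.full(len(bases), 40)
        return Read(id=id, bases=bases, quals=quals, mask=mask, **kw)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def random_dna(rng):
    def _dna(n, r=None):
        r = rng if r is None else r
        return "".join("ACGT"[i] for i in r.integers(0, 4, n))

    return _dna
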
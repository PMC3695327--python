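import numpy as np
import pytest

from msblup.pedigree_algebra import parse_pedigree


@pytest.fixture
def trio_ped():
    """Two founders and one offspring."""
    return parse_pedigree([("b1", None, None), ("b2", None, None),
                           ("c", "b1", "b2")])


@pytest.fixture
def five_ped():
    """Three founders; d4 = b1 x b2; d5 = d4 x b3."""
    return parse_pedigree([
        ("b1", None, None), ("b2", None, None), ("b3", None, None),
        ("d4", "b1", "b2"), ("d5", "d4", "b3"),
    ])


def random_pedigree_records(rng, n_individuals, p_base=0.3, p_self=0.05):
    """Random valid pedigree records: each individual is a founder or the
    offspring of two (possibly identical, for selfing) earlier individuals."""
    records = []
    for i in range(n_individuals):
        iid = f"i{i}"
        if i < 2 or rng.random() < p_base:
            records.append((iid, None, None))
        else:
            s = f"i{rng.integers(0, i)}"
            d = s if rng.random() < p_self else f"i{rng.integers(0, i)}"
            records.append((iid, s, d))
    return records


@pytest.fixture
def make_random_pedigree():
    def _make(seed, n=20, **kw):
        rng = np.random.default_rng(seed)
        return parse_pedigree(random_pedigree_records(rng, n, **kw))
    return _make


@pytest.fixture
def make_random_markers(make_random_pedigree):
    from msblup.marker_data import MarkerMatrix

    def _make(seed, n=15, n_markers=8, **kw):
        ped = make_random_pedigree(seed, n=n, **kw)
        rng = np.random.default_rng(seed + 7)
        W = rng.integers(0, 3, size=(ped.n, n_markers)).astype(float)
        ids = tuple(f"m{j}" for j in range(n_markers))
        return MarkerMatrix(W=W, marker_ids=ids, ped=ped)
    return _make
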
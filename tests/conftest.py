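import numpy as np
import pytest

from bhcn.synthetic import toy_network


@pytest.fixture
def toy():
    """The 3x3, 5-edge worked example (T1) with its similarity matrices."""
    return toy_network()


@pytest.fixture
def toy_assoc(toy):
    return toy[0]


def random_bipartite(rng, max_d=8, max_m=8):
    """One random Boolean association matrix for oracle comparisons."""
    n_d = rng.integers(1, max_d + 1)
    n_m = rng.integers(1, max_m + 1)
    p = rng.choice(np.arange(0.1, 1.0, 0.1))
    return (rng.random((n_d, n_m)) < p).astype(np.int8)


def brute_force_ncn(a):
    """Exhaustive enumeration of simple length-3 paths d_i->m'->d'->m_j.

    Independent oracle for the closed-form walk-count computation: loops
    over every intermediate pair with all four nodes distinct.
    """
    n_d, n_m = a.shape
    out = np.zeros((n_d, n_m), dtype=np.int64)
    for i in range(n_d):
        for j in range(n_m):
            count = 0
            for mp in range(n_m):
                if mp == j or not a[i, mp]:
                    continue
                for dp in range(n_d):
                    if dp == i or not a[dp, mp]:
                        continue
                    if a[dp, j]:
                        count += 1
            out[i, j] = count
    return out
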
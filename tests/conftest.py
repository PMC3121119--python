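import numpy as np
import pytest

import hifmap


@pytest.fixture(scope="session")
def bundle():
    return hifmap.load_fixture_bundle()


@pytest.fixture(scope="session")
def hre_matrix(bundle):
    """HRE score matrix built from every bundled 18-mer site."""
    return hifmap.build_hre_matrix(bundle.hre_site_set())


def random_score_matrix(rng: np.random.Generator, width: int, matrix_id="rand"):
    """A random frequency-mode score matrix for property tests."""
    counts = rng.integers(0, 20, size=(4, width)).astype(float)
    counts[rng.integers(0, 4), :] += 1  # no empty columns
    freq = (counts + 0.01) / (counts.sum(axis=0) + 0.04)
    return hifmap.MotifMatrix(matrix_id=matrix_id, form="score", values=freq)
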
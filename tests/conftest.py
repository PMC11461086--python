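import numpy as np
import pandas as pd
import pytest

from paleopop.containers import GenotypeMatrix, make_labels


def toy_matrix(dosages, sample_prefix="S"):
    """Small GenotypeMatrix from a literal dosage list (rows = samples)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                          "ref": "A", "alt": "G"})
    samples = np.array([f"{sample_prefix}{i + 1}" for i in range(n)],
                       dtype=object)
    return GenotypeMatrix(samples=samples, sites=sites, dosages=d)


@pytest.fixture
def three_by_three():
    return toy_matrix([[0, 1, 2], [1, 0, 2], [2, 2, 0]])


@pytest.fixture
def two_pop_labels():
    def _make(matrix, pops):
        return make_labels(matrix.samples, pops, "modern")
    return _make
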
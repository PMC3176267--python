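import numpy as np
import pytest

from physprot import (
    FeatureMatrix,
    PropertyTable,
    SequenceRecord,
    SynthSpec,
    make_benchmark,
)
from physprot.io_formats import AAINDEX_ORDER


@pytest.fixture
def two_record_fasta(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">p1 first protein\nmk*v\n>p2\nAC\nDE\n")
    return p


@pytest.fixture
def minimal_aaindex(tmp_path):
    """Two AAindex1 records: one with values 1..20, one with an NA slot for W."""
    vals = "   1.0    2.0    3.0    4.0    5.0    6.0    7.0    8.0    9.0   10.0\n" \
           "  11.0   12.0   13.0   14.0   15.0   16.0   17.0   18.0   19.0   20.0\n"
    vals_na = "   0.1    0.2    0.3    0.4    0.5    0.6    0.7    0.8    0.9    1.0\n" \
              "   1.1    1.2    1.3    1.4    1.5    1.6    1.7     NA    1.9    2.0\n"
    p = tmp_path / "mini.aaindex1"
    p.write_text(
        "H TEST0001\nD ordered test index\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        + vals + "//\n"
        "H TEST0002\nD index with NA for W\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        + vals_na + "//\n"
    )
    return p


def table_from_values(accession="T1", **kv):
    """PropertyTable with the given residue values, NaN elsewhere unless
    a 'default' keyword sets the fill."""
    default = kv.pop("default", float("nan"))
    values = {aa: float(kv.get(aa, default)) for aa in AAINDEX_ORDER}
    return PropertyTable(accession=accession, values=values)


@pytest.fixture
def labeled_matrix():
    """Tiny well-separated two-class matrix: f0 separates, f1 is constant."""
    rng = np.random.default_rng(7)
    n = 10
    X = np.zeros((2 * n, 3))
    X[:n, 0] = rng.normal(0.0, 0.05, n)
    X[n:, 0] = rng.normal(1.0, 0.05, n)
    X[:, 1] = 3.14
    X[:, 2] = rng.normal(0.0, 1.0, 2 * n)
    y = np.array([-1] * n + [1] * n)
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(2 * n)],
        feature_ids=["sep", "const", "noise"],
        X=X,
        y=y,
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """Session-scoped synthetic benchmark for pipeline-level tests."""
    spec = SynthSpec(n_pos=40, n_neg=40, n_tables=20, n_informative=5,
                     delta=0.4, seed=11)
    return make_benchmark(spec, n_test_pos=25, n_test_neg=25)
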
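import numpy as np
import pytest

from longsamgsr.data import LongitudinalExpressionSet


def make_dataset(G=5, n1=3, n0=3, T=2, seed=0, mask=None):
    """Small random labeled dataset; labels are the first n1 subjects."""
    rng = np.random.default_rng(seed)
    n = n1 + n0
    expr = rng.normal(size=(G, n, T))
    m = np.ones_like(expr, dtype=bool) if mask is None else mask
    labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    return LongitudinalExpressionSet(expr, m, labels)


@pytest.fixture
def small_ds():
    return make_dataset()


@pytest.fixture
def expr_tsv(tmp_path):
    """3-gene x 4-sample expression TSV + matching design TSV (2 subj x 2 t)."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene_id\tsA_t1\tsA_t2\tsB_t1\tsB_t2\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t5.0\t6.0\t7.0\t8.0\n"
        "g3\t-1.5\t0.5\t2.5\t1.5\n")
    design = tmp_path / "design.tsv"
    design.write_text(
        "sample_id\tsubject_id\ttime_index\tphenotype\n"
        "sA_t1\tA\t1\t1\n"
        "sA_t2\tA\t2\t1\n"
        "sB_t1\tB\t1\t0\n"
        "sB_t2\tB\t2\t0\n")
    return expr, design
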
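import numpy as np
import pytest

from dynsig.core_io import ExpressionMatrix, PairedCohort


def make_matrix(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return ExpressionMatrix(
        gene_ids or [f"G{i}" for i in range(g)],
        sample_ids or [f"S{j}" for j in range(s)],
        values,
    )


def make_cohort(pre, post, response=None, covariates=None) -> PairedCohort:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    g, n = pre.shape
    genes = [f"G{i}" for i in range(g)]
    tumors = [f"T{j}" for j in range(n)]
    return PairedCohort(
        ExpressionMatrix(genes, tumors, pre),
        ExpressionMatrix(genes, tumors, post),
        tumors,
        response,
        covariates,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
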
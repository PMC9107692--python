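import warnings

import numpy as np
import pandas as pd
import pytest

from lumipipe import molecular_scoring as ms
from lumipipe.expression_qc import normalize, qc_filter_samples
from lumipipe.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort600():
    """One medium synthetic cohort shared across tests (train/test splits etc.)."""
    return generate_cohort(CohortSpec(n_patients=600, seed=11))


@pytest.fixture(scope="session")
def normalized600(cohort600):
    filtered, _ = qc_filter_samples(cohort600.panel)
    return normalize(filtered)


@pytest.fixture(scope="session")
def centroid_model600(cohort600, normalized600):
    """Centroids trained on the first 400 samples of the shared cohort."""
    train_ids = normalized600.values.index[:400]
    nm_train = _subset_nm(normalized600, train_ids)
    labels = cohort600.clinical["true_subtype"].loc[train_ids]
    return ms.train_centroids(nm_train, labels)


def _subset_nm(nm, ids):
    from lumipipe.expression_qc import NormalizedMatrix

    return NormalizedMatrix(
        values=nm.values.loc[ids], log2=nm.log2.loc[ids],
        centering=nm.centering, standardized=nm.standardized,
        zero_variance_genes=nm.zero_variance_genes,
    )


@pytest.fixture(scope="session")
def scores600(cohort600, normalized600, centroid_model600):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ms.score_cohort(normalized600, centroid_model600)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def toy_panel():
    """Tiny 3-sample panel over the default 72 genes with nonzero counts."""
    from lumipipe import config
    from lumipipe.expression_qc import ExpressionPanel

    r = np.random.default_rng(5)
    counts = pd.DataFrame(
        r.integers(5, 2000, size=(3, len(config.ALL_GENES))),
        index=["A", "B", "C"], columns=list(config.ALL_GENES),
    )
    return ExpressionPanel(counts=counts, gene_roles=config.default_gene_roles())
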
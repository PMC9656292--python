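import numpy as np
import pytest

from mirsubnet.io_core import ExpressionMatrix
from mirsubnet.synthetic_data import SyntheticCohortSpec, generate_cohort


def make_matrix(values, feature_ids=None, sample_ids=None, detected=None,
                scale_tag="log2"):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samp)]
    if detected is None:
        detected = np.ones_like(values, dtype=bool)
    return ExpressionMatrix(feature_ids, sample_ids, values, detected, scale_tag)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small cohort shared by read-only tests."""
    spec = SyntheticCohortSpec(
        rng_seed=42, n_mirs=40, n_genes=80, n_edges=15,
        signature_block_size=8, missing_rate=0.0,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-geometry cohort (88 tumors + 19 normals, 176 miRs, 1722 genes)."""
    spec = SyntheticCohortSpec(rng_seed=7)
    return spec, generate_cohort(spec)
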
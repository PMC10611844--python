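import warnings

import numpy as np
import pytest

from petqml.cohorts import CohortSpec, generate_cohort
from petqml.cv import make_cv_scheme
from petqml.prep import spearman_redundancy_reduce
from petqml.quantum import amplitude_encode
from petqml.study import prepare_fold

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 121-lesion prostate-like cohort with moderate separation."""
    return generate_cohort(
        CohortSpec(n_patients=95, n_samples=121, delta=1.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_fold(small_cohort):
    """One prepared fold (SRT 0.7, 8 features) of the small cohort."""
    scheme = make_cv_scheme(small_cohort, seed=11)
    reduced, _ = spearman_redundancy_reduce(small_cohort, 0.7)
    return prepare_fold(reduced, scheme.folds[0], 8)


def random_states(n, dim, seed, complex_valued=False):
    """Random unit-norm amplitude-encoded states."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = rng.standard_normal(dim)
        if complex_valued:
            v = v + 1j * rng.standard_normal(dim)
        out.append(amplitude_encode(v / np.linalg.norm(v)))
    return out
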
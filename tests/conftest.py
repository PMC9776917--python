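import itertools

import numpy as np
import pytest

from cxragree import fig1_lung_scheme


def pairwise_observed_agreement(column: np.ndarray) -> float:
    """Brute-force oracle: mean over cases of pairwise rater concordance.

    Enumerates all n(n-1)/2 rater pairs per case; independent of the
    closed-form implementation it checks.
    """
    col = np.asarray(column)
    n = col.shape[1]
    per_case = []
    for row in col:
        agree = [
            1.0 if row[a] == row[b] else 0.0
            for a, b in itertools.combinations(range(n), 2)
        ]
        per_case.append(sum(agree) / len(agree))
    return float(np.mean(per_case))


def random_binary_columns(rng, n_cases, n_raters, p=None):
    p = rng.uniform(0.05, 0.95) if p is None else p
    return (rng.random((n_cases, n_raters)) < p).astype(np.uint8)


@pytest.fixture(scope="session")
def scheme():
    return fig1_lung_scheme()


@pytest.fixture(scope="session")
def categories(scheme):
    return scheme.category_columns()
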
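import numpy as np
import pytest

from uromet.containers import AbundanceMatrix
from uromet.synthetic_data import SyntheticSpec, generate_dataset


def make_matrix(values, y, scale="linear", known=None):
    """Small-matrix helper: ids generated, annotation defaults to known."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ann = ["known" if (known is None or known[j]) else "unknown" for j in range(p)]
    return AbundanceMatrix(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        feature_ids=tuple(f"f{j}" for j in range(p)),
        annotation=tuple(ann),
        y=np.asarray(y, dtype=int),
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 30+15-sample, 20-feature cohort with planted structure."""
    spec = SyntheticSpec(
        n_case=30,
        n_control=15,
        p_known=14,
        p_unknown=6,
        effects=((0, 2.0), (1, -2.0)),
        n_common_edges=4,
        n_diff_edges=2,
        edge_strength=0.4,
        seed=11,
    )
    matrix, truth = generate_dataset(spec)
    return spec, matrix, truth
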
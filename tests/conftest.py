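import numpy as np
import pytest

from braingpc import CohortSpec, Group, generate_cohort
from braingpc.cohort import default_thinning_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with widespread thinning ~3x the residual SD in the case and
    carrier groups — strong enough that the contrast must be recoverable."""
    spec = CohortSpec(
        group_sizes={
            Group.HC: 16, Group.SCZ: 16, Group.T_MINUS: 12, Group.T_PLUS: 10,
        },
        n_features=40,
        noise_sd=0.12,
        effect=default_thinning_pattern(40, 0.36),
        carrier_effect_scale=1.0,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Balanced two-group cohort with no group effect."""
    spec = CohortSpec(
        group_sizes={Group.HC: 10, Group.SCZ: 10},
        n_features=12,
        effect=None,
        seed=5,
    )
    return generate_cohort(spec)


def contrast_arrays(cohort, neg_group, pos_group):
    """X, y, ids for a two-group contrast, negatives first."""
    ids, ys = [], []
    for grp, lab in ((neg_group, -1.0), (pos_group, 1.0)):
        for r in cohort.records:
            if r.group is grp:
                ids.append(r.subject_id)
                ys.append(lab)
    idx = {s: i for i, s in enumerate(cohort.table.subject_ids)}
    X = cohort.table.values[[idx[s] for s in ids]]
    return X, np.array(ys), ids
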
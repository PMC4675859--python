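import numpy as np
import pytest

from watermaze.cohort import CohortDesign, GroupBehavior, GroupSpec
from watermaze.geometry import PoolGeometry
from watermaze.simulate import EffectSpec, generate_metric_table


@pytest.fixture(scope="session")
def geometry() -> PoolGeometry:
    return PoolGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


_PAIRS = [("WT", "NT"), ("TS", "NT"), ("WT", "EE"), ("TS", "EE"),
          ("WT", "EGCG"), ("TS", "EGCG"), ("WT", "EE-EGCG"), ("TS", "EE-EGCG")]


def make_design(sizes=(6, 6), n_sessions=5, seed=0, behavior=None, **kwargs) -> CohortDesign:
    """Small WT/TS-style design for unit tests."""
    groups = tuple(
        GroupSpec(*_PAIRS[k], n, behavior or GroupBehavior())
        for k, n in enumerate(sizes)
    )
    return CohortDesign(
        groups=groups, n_acquisition_sessions=n_sessions, seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def paper_sized_records():
    """Session-mean metric records for the full 8-group, 86-subject design
    (fast path, exchangeable subjects)."""
    from watermaze.cohort import default_cohort

    design = default_cohort(seed=11)
    return design, generate_metric_table(design, EffectSpec.null(design), seed=11)


@pytest.fixture
def two_group_records():
    design = make_design(sizes=(10, 10), seed=5)
    return design, generate_metric_table(design, EffectSpec.null(design), seed=5)
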
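"""Shared fixtures: small study pairs built from summary statistics."""

import numpy as np
import pytest

from repmarket.effect_size import TestSummary
from repmarket.indicators import StudyPair


def two_sample_summary(
    study_id="S1",
    role="original",
    t=3.0,
    n=100,
    same_direction=None,
):
    """A balanced two-sample t-test summary."""
    from scipy.stats import t as t_dist

    df = 2 * n - 2
    return TestSummary(
        study_id=study_id,
        role=role,
        family="two_sample_t",
        statistic=abs(t),
        df=df,
        n1=n,
        n2=n,
        p_two_sided=float(2 * t_dist.sf(abs(t), df)),
        same_direction=same_direction,
    )


def make_pair(t_o=3.0, n_o=100, t_r=3.0, n_r=350, same_direction=True) -> StudyPair:
    orig = two_sample_summary("S1", "original", t=t_o, n=n_o)
    rep = two_sample_summary("S1", "replication", t=t_r, n=n_r, same_direction=same_direction)
    return StudyPair.from_summaries(orig, rep)


@pytest.fixture
def pair():
    return make_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
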
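import numpy as np
import pytest

import preftrial as pt
from preftrial import simulate as sim
from preftrial.trial_data import _summary_from_arrays


@pytest.fixture(scope="session")
def example():
    return pt.example_trial()


@pytest.fixture(scope="session")
def example_recs():
    return pt.example_records()


def draw_summary(params: pt.ModelParams, rng) -> pt.TrialSummary:
    """One simulated trial collapsed straight to its six-cell summary."""
    return _summary_from_arrays(*sim._draw_columns(params, rng))


def random_summary(rng) -> pt.TrialSummary:
    """A structurally valid random summary for algebraic property checks."""
    m1 = int(rng.integers(5, 60))
    m2 = int(rng.integers(5, 60))
    m3 = int(rng.choice([0, int(rng.integers(4, 100))]))
    n13 = int(rng.integers(2, m3 - 1)) if m3 >= 4 else 0
    n23 = m3 - n13
    n1 = int(rng.integers(5, 60))
    n2 = int(rng.integers(5, 60))
    means = rng.uniform(-30, 30, 6)
    sds = rng.uniform(0.0, 15.0, 6)
    nan = float("nan")
    return pt.TrialSummary(
        m1=m1, m2=m2, m3=m3, n13=n13, n23=n23, n1=n1, n2=n2,
        xbar1=means[0], xbar2=means[1],
        vbar1=means[2] if m3 else nan, vbar2=means[3] if m3 else nan,
        ybar1=means[4], ybar2=means[5],
        s11=sds[0], s22=sds[1],
        s13=sds[2] if m3 else nan, s23=sds[3] if m3 else nan,
        s1=sds[4], s2=sds[5],
    )
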
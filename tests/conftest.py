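import io

import numpy as np
import pytest

import contextfpc as cf


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_csv():
    """Two groups of two rows each."""
    return io.StringIO("gid,score,ses\na,0,0\na,2,2\nb,1,1\nb,3,3\n")


def make_table(model=cf.Model.MLM, bal=True, N=20, icc=0.25, R=10.0,
               g=100, r=0.5, seed=0):
    """One simulated sample table under the study's generating process."""
    spec = cf.ModelSpec(model)
    cond = cf.Condition(model, bal, N, icc, R, g, r)
    gp = cf.GeneratorParams.for_cell(model, R, icc)
    gen = np.random.default_rng(seed)
    rosters = cf.generate_groups(spec, cond, gp, gen)
    return cf.sample_within(rosters, r, gen), spec, gp


@pytest.fixture
def mlm_table():
    return make_table()
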
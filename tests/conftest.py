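import numpy as np
import pandas as pd
import pytest

import epiclock as ec
from epiclock.divergence import PAIR_COLUMNS


def make_sample(sample_id, states, seqname="chr1", context="CG", positions=None):
    """MethylomeSample from a flat array of states in {0, 0.5, 1}."""
    states = np.asarray(states, dtype=float)
    n = len(states)
    if positions is None:
        positions = np.arange(1, n + 1)
    idx = pd.MultiIndex.from_arrays(
        [
            np.repeat(seqname, n),
            np.asarray(positions, dtype=np.int64),
            np.repeat("+", n),
            np.repeat(context, n),
        ],
        names=["seqname", "position", "strand", "context"],
    )
    return ec.MethylomeSample(sample_id, pd.Series(states, index=idx))


def analytic_dataset(spec, params, time_triples, p1_obs, p3_obs, p_bar_1=None):
    """DivergenceDataset whose divergences are exact model expectations."""
    pi = ec.founder_distribution(p1_obs, p3_obs, params.gamma)
    rows = []
    for k, (ti, tj, tij) in enumerate(time_triples):
        d = ec.expected_divergence(params, spec, (ti, tj, tij), pi) + params.c
        rows.append((f"s{k}a", f"s{k}b", ti, tj, tij, (ti - tij) + (tj - tij), d, 1000))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if p_bar_1 is None:
        p_bar_1 = ec.equilibrium_uu(spec, params) if params.alpha + params.beta > 0 else p1_obs
    return ec.DivergenceDataset(pairs, p1_obs, p3_obs, p_bar_1)


TIME_TRIPLES = [
    (5, 5, 1), (10, 10, 1), (20, 20, 1), (30, 30, 1), (10, 20, 5),
    (15, 30, 10), (30, 30, 10), (8, 25, 1), (12, 18, 3), (25, 25, 20),
]


@pytest.fixture
def chain_pedigree():
    """Founder F(t=0) -> A(t=3) -> B(t=31), all sampled."""
    return ec.build_pedigree(
        [("F", 0, "S_F"), ("A", 3, "S_A"), ("B", 31, "S_B")],
        [("F", "A"), ("A", "B")],
    )


@pytest.fixture
def clonal_noisefree_data():
    spec = ec.ModelSpec("clonal", "ABneutral")
    params = ec.EpimutationParams(5e-3, 2e-2, gamma=0.3, c=0.01)
    return spec, params, analytic_dataset(spec, params, TIME_TRIPLES, 0.65, 0.30)
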
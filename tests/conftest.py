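import numpy as np
import pandas as pd
import pytest

from m6adecay.core_io import CountMatrix, SampleMeta
from m6adecay.simulate import SimulationParams, simulate_transcriptome


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_params):
    return simulate_transcriptome(default_params)


@pytest.fixture(scope="session")
def default_study(default_params):
    from m6adecay.pipeline import simulate_study

    return simulate_study(default_params)


@pytest.fixture(scope="session")
def default_result(default_study):
    from m6adecay.pipeline import run_analysis

    s = default_study
    return run_analysis(s.merip, s.decay, s.spikes, s.rip)


def make_matrix(counts: dict[str, list], metas: list[tuple]) -> CountMatrix:
    """counts: sample_id -> per-feature counts; metas: SampleMeta arg tuples."""
    n = len(next(iter(counts.values())))
    idx = pd.Index([f"g{i}" for i in range(n)])
    df = pd.DataFrame(counts, index=idx)
    return CountMatrix(df, [SampleMeta(*m) for m in metas])


@pytest.fixture
def tiny_merip():
    """2 conditions x {input, IP}, one replicate each, 2 features."""
    return make_matrix(
        {
            "c_in": [200, 800],
            "c_ip": [800, 200],
            "p_in": [800, 200],
            "p_ip": [200, 800],
        },
        [
            ("c_in", "control", "input"),
            ("c_ip", "control", "IP"),
            ("p_in", "patient", "input"),
            ("p_ip", "patient", "IP"),
        ],
    )
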
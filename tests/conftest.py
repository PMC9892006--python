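import numpy as np
import pandas as pd
import pytest

from dopaseq.generate import make_generative_params, simulate_syllable_sequence

K = 10


def uniform_base(k: int = K) -> np.ndarray:
    T = np.ones((k, k)) / (k - 1)
    np.fill_diagonal(T, 0.0)
    return T


@pytest.fixture(scope="session")
def coupled_params():
    """Generator with the usage coupling on, uniform Markov prior, dopamine
    means spanning -1..+1 z with unit s.d."""
    return make_generative_params(K, seed=1, base_transitions=uniform_base(),
                                  alpha_a_true=1.0)


@pytest.fixture(scope="session")
def null_params():
    return make_generative_params(K, seed=1, base_transitions=uniform_base(),
                                  alpha_a_true=0.0)


@pytest.fixture(scope="session")
def coupled_sessions(coupled_params):
    return [simulate_syllable_sequence(coupled_params, 5000, seed=1000 + i)
            for i in range(6)]


@pytest.fixture(scope="session")
def null_sessions(null_params):
    return [simulate_syllable_sequence(null_params, 4000, seed=2000 + i)
            for i in range(4)]


def peak_table(sessions, mouse="m0", frames_per_step=12):
    rows = []
    for i, (labels, da) in enumerate(sessions):
        n = len(labels)
        rows.append(pd.DataFrame({
            "mouse": mouse, "session": f"s{i}",
            "instance_index": np.arange(n), "syllable": labels,
            "onset_frame": np.arange(n) * frames_per_step,
            "duration_frames": frames_per_step,
            "peak": da, "velocity": np.nan,
        }))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def coupled_table(coupled_sessions):
    return peak_table(coupled_sessions)


@pytest.fixture(scope="session")
def null_table(null_sessions):
    return peak_table(null_sessions)
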
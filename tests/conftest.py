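import numpy as np
import pandas as pd
import pytest

from poifinder import EpisodeModel, FeatureSeries, generate, regularize


@pytest.fixture
def feature_csv(tmp_path):
    """Tiny 3-row feature CSV with columns t,h9,a1."""
    path = tmp_path / "features.csv"
    path.write_text("t,h9,a1\n0,0.82,0.43\n1,0.83,0.42\n2,0.81,0.44\n")
    return path


@pytest.fixture
def small_series():
    rng = np.random.default_rng(42)
    values = rng.normal([0.82, 0.43, 0.09, 1.04], 0.01, size=(50, 4))
    return FeatureSeries(
        start_time=0.0, step=1.0, names=["h9", "a1", "a3", "a4"], values=values
    )


@pytest.fixture
def synthetic_run():
    """One default synthetic recording, regularized, with its events."""
    raw, events = generate(EpisodeModel(seed=11))
    return regularize(raw), events


@pytest.fixture
def table1_samples():
    """One-row neutral/smiling tables holding the measured state averages
    of an expressive adult face."""
    neutral = pd.DataFrame(
        {"h9": [0.8199], "a1": [0.4270], "a3": [0.0901], "a4": [1.0431]}
    )
    smiling = pd.DataFrame(
        {"h9": [0.8914], "a1": [0.3981], "a3": [0.0503], "a4": [0.9817]}
    )
    return neutral, smiling
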
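import numpy as np
import pytest

from thetaflow.data import ChannelInfo, TrialInfo, TrialSet, select_trials
from thetaflow.simulate import SynthConfig, simulate_participant


def make_trialset(
    data: np.ndarray,
    fs: float = 200.0,
    t0_offset: float | None = None,
    roles: list[str] | None = None,
) -> TrialSet:
    """Wrap a raw (trials, channels, samples) array in a TrialSet."""
    n_trials, n_channels, n_samples = data.shape
    if t0_offset is None:
        t0_offset = -n_samples / fs
    roles = roles or ["scalp"] * n_channels
    channels = [ChannelInfo(name=f"ch{i}", role=roles[i]) for i in range(n_channels)]
    trials = [
        TrialInfo(set_size=6, correct=True, probe_in=bool(i % 2), rt=1.0)
        for i in range(n_trials)
    ]
    return TrialSet(data=data, fs=fs, t0_offset=t0_offset,
                    channels=channels, trials=trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def focus_pair_cfg() -> SynthConfig:
    """Pair-level study conditions: hippocampus + the grid coupling focus."""
    return SynthConfig(grid_subset=[("C", 2)], n_trials_per_participant=80, seed=7)


@pytest.fixture(scope="session")
def focus_participant(focus_pair_cfg) -> TrialSet:
    return simulate_participant(focus_pair_cfg, 0)


@pytest.fixture(scope="session")
def focus_correct_highload(focus_participant) -> TrialSet:
    return select_trials(focus_participant, set_sizes={6, 8}, correct=True)
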
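"""Trial data model, preprocessing and I/O."""

import numpy as np
import pytest

from thetaflow.data import (
    ChannelInfo,
    ConfigurationError,
    EpochWindow,
    ReferenceScheme,
    TrialInfo,
    TrialSet,
    ValidationError,
    downsample,
    reject_artifacts,
    rereference,
    select_trials,
)
from thetaflow.io import edf_quantization_step, load_trials, save_trials

from conftest import make_trialset


def _tone(f, fs, n, amp=1.0):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs)


def _fft_amp(x, fs, f):
    w = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * w)) / np.sum(w) * 2
    grid = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(grid - f))]


# -- epoch windows ----------------------------------------------------------

def test_window_slice_is_half_open(rng):
    ts = make_trialset(rng.standard_normal((2, 1, 600)), fs=100.0, t0_offset=-6.0)
    sl = ts.window_slice(EpochWindow("fixation", -6.0, -5.0))
    assert (sl.start, sl.stop) == (0, 100)  # exactly 1 s, boundary excluded
    nxt = ts.window_slice(EpochWindow("encoding", -5.0, -3.0))
    assert nxt.start == sl.stop  # adjacent windows share no sample


def test_invalid_window_and_metadata():
    with pytest.raises(ValidationError):
        EpochWindow("bad", 0.0, 0.0)
    with pytest.raises(ValidationError):
        ChannelInfo(name="g", role="ecog_grid", grid_pos=None)
    with pytest.raises(ValidationError):
        ChannelInfo(name="g", role="scalp", grid_pos=("A", 1))
    with pytest.raises(ValidationError):
        TrialInfo(set_size=5, correct=True, probe_in=True, rt=1.0)


# -- fixture / EDF round trips ----------------------------------------------

def test_fixture_roundtrip_bit_exact(rng, tmp_path):
    ts = make_trialset(rng.standard_normal((2, 3, 100)).astype("<f4").astype(float))
    path = save_trials(ts, tmp_path / "fix")
    ts2 = load_trials(path)
    assert ts2.data.shape == (2, 3, 100)
    np.testing.assert_array_equal(ts.data, ts2.data)
    assert [c.name for c in ts2.channels] == [c.name for c in ts.channels]
    assert ts2.trials == ts.trials
    assert ts2.fs == ts.fs and ts2.t0_offset == ts.t0_offset


def test_single_trial_roundtrip_and_empty_error(rng, tmp_path):
    ts = make_trialset(rng.standard_normal((1, 2, 50)).astype("<f4").astype(float))
    ts2 = load_trials(save_trials(ts, tmp_path / "one"))
    np.testing.assert_array_equal(ts.data, ts2.data)
    empty = TrialSet(
        data=np.zeros((0, 2, 50)), fs=200.0, t0_offset=-0.25,
        channels=ts.channels, trials=[],
    )
    with pytest.raises(ValidationError):
        save_trials(empty, tmp_path / "none")


def test_missing_sidecar_is_format_error(rng, tmp_path):
    ts = make_trialset(rng.standard_normal((2, 2, 40)))
    path = save_trials(ts, tmp_path / "x")
    (tmp_path / "x.json").unlink()
    with pytest.raises(ValidationError, match="sidecar"):
        load_trials(path)


def test_edf_roundtrip_within_quantization(rng, tmp_path):
    ts = make_trialset(50.0 * rng.standard_normal((3, 2, 500)), fs=500.0)
    path = save_trials(ts, tmp_path / "e", format="edf")
    ts2 = load_trials(path, format="edf")
    step = edf_quantization_step(ts)
    assert np.abs(ts2.data - ts.data).max() <= step * (0.5 + 1e-6)
    assert ts2.trials == ts.trials


# -- re-referencing ---------------------------------------------------------

def _lfp_set(rng, n_ch=3):
    data = rng.standard_normal((4, n_ch, 200))
    channels = [ChannelInfo(name=f"d{i}", role="hippocampal_lfp") for i in range(n_ch)]
    trials = [TrialInfo(set_size=6, correct=True, probe_in=True, rt=1.0)] * 4
    return TrialSet(data=data, fs=200.0, t0_offset=-1.0, channels=channels, trials=trials)


def test_rereference_channel_equal_to_reference_gives_zero(rng):
    ts = _lfp_set(rng, 2)
    ts.data[:, 0, :] = ts.data[:, 1, :]
    out = rereference(ts, ReferenceScheme({"hippocampal_lfp": ("d1",)}))
    assert out.n_channels == 1  # reference dropped
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_rereference_difference_series(rng):
    ts = _lfp_set(rng, 2)
    out = rereference(ts, ReferenceScheme({"hippocampal_lfp": ("d1",)}))
    np.testing.assert_allclose(out.data[:, 0], ts.data[:, 0] - ts.data[:, 1])


def test_averaged_mastoid_scheme_elementwise(rng):
    data = rng.standard_normal((3, 5, 150))
    channels = [ChannelInfo(name=n, role="scalp") for n in ["F3", "C3", "O1", "M1", "M2"]]
    trials = [TrialInfo(set_size=6, correct=True, probe_in=True, rt=1.0)] * 3
    ts = TrialSet(data=data, fs=200.0, t0_offset=-0.75, channels=channels, trials=trials)
    out = rereference(ts, ReferenceScheme({"scalp": ("M1", "M2")}))
    mast = (data[:, 3] + data[:, 4]) / 2
    for i in range(3):
        np.testing.assert_allclose(out.data[:, i], data[:, i] - mast)


def test_rereference_is_linear(rng):
    ts = _lfp_set(rng, 3)
    scheme = ReferenceScheme({"hippocampal_lfp": ("d2",)})
    scaled = TrialSet(data=3.0 * ts.data, fs=ts.fs, t0_offset=ts.t0_offset,
                      channels=ts.channels, trials=ts.trials)
    np.testing.assert_allclose(
        rereference(scaled, scheme).data, 3.0 * rereference(ts, scheme).data
    )


def test_shared_lfp_ecog_reference_rejected():
    with pytest.raises(ConfigurationError, match="distinct"):
        ReferenceScheme({"hippocampal_lfp": ("dref",), "ecog_grid": ("dref",)})


# -- downsampling -----------------------------------------------------------

def test_downsample_preserves_passband_tone():
    ts = make_trialset(_tone(6, 500, 3000)[None, None, :], fs=500.0)
    out = downsample(ts, 40.0)
    assert out.fs == 40.0
    assert abs(out.n_samples - ts.n_samples * 40 / 500) <= 1
    assert abs(_fft_amp(out.data[0, 0], 40, 6) - 1.0) < 0.01


def test_downsample_dc_unchanged():
    ts = make_trialset(np.full((1, 1, 1000), 7.5), fs=500.0)
    out = downsample(ts, 100.0)
    np.testing.assert_allclose(out.data, 7.5, atol=1e-3)


def test_downsample_attenuates_above_new_nyquist():
    ts = make_trialset(_tone(30, 500, 5000)[None, None, :], fs=500.0)
    out = downsample(ts, 40.0)
    # 30 Hz folds to 10 Hz; the designed stopband is >= 60 dB, assert 40 dB
    alias = _fft_amp(out.data[0, 0, 20:-20], 40, 10)
    assert 20 * np.log10(alias + 1e-300) < -40


def test_downsample_rejects_upsampling(rng):
    ts = make_trialset(rng.standard_normal((1, 1, 100)), fs=40.0)
    with pytest.raises(ConfigurationError):
        downsample(ts, 200.0)


# -- artifact rejection -----------------------------------------------------

def test_planted_spike_rejected(rng):
    data = rng.standard_normal((20, 3, 300))
    data[7, 1, 150] = 10 * np.abs(data).max()
    ts = make_trialset(data)
    out, rejected = reject_artifacts(ts, amp_threshold=500.0, z_threshold=6.0)
    assert list(rejected) == [7]
    assert out.n_trials == 19


def test_homogeneous_trials_not_rejected(rng):
    ts = make_trialset(rng.standard_normal((15, 2, 200)))
    out, rejected = reject_artifacts(ts, amp_threshold=np.inf, z_threshold=50.0)
    assert rejected.size == 0 and out.n_trials == 15


def test_zero_threshold_is_error(rng):
    ts = make_trialset(rng.standard_normal((3, 1, 100)))
    with pytest.raises(ConfigurationError):
        reject_artifacts(ts, amp_threshold=0.0)
    with pytest.raises(ValidationError, match="every trial"):
        reject_artifacts(ts, amp_threshold=1e-9, z_threshold=1e9)


# -- trial selection --------------------------------------------------------

def test_select_trials_matches_metadata_tally(rng):
    n = 50
    sizes = rng.choice([4, 6, 8], size=n)
    correct = rng.random(n) < 0.6
    trials = [
        TrialInfo(set_size=int(s), correct=bool(c), probe_in=True, rt=1.0)
        for s, c in zip(sizes, correct)
    ]
    ts = TrialSet(data=rng.standard_normal((n, 1, 50)), fs=100.0, t0_offset=-0.5,
                  channels=[ChannelInfo(name="c", role="scalp")], trials=trials)
    out = select_trials(ts, set_sizes={6, 8}, correct=True)
    expected = int(np.sum(np.isin(sizes, [6, 8]) & correct))
    assert out.n_trials == expected
    assert all(t.correct and t.set_size in (6, 8) for t in out.trials)

    identity = select_trials(ts, set_sizes={4, 6, 8}, correct=None)
    assert identity.n_trials == n
    with pytest.raises(ValidationError):
        select_trials(ts, set_sizes=set())
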
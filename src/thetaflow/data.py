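"""Trial data model and preprocessing for epoched multichannel recordings.

The pipeline's universal currency is the :class:`TrialSet`: an array of
epoched trials (trials x channels x samples, microvolts) plus channel and
trial metadata.  The epoch clock is anchored at probe onset (t = 0 s); a full
trial spans [-6, 0] s with fixation [-6, -5] s, encoding (stimulus
presentation) [-5, -3] s and maintenance (memory delay) [-3, 0] s.  Analyses
of the maintenance period use its last two seconds, [-2, 0] s.

All epoch windows are half-open intervals [t_start, t_end) so that adjacent
windows never share a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal


class ValidationError(ValueError):
    """Raised when a TrialSet or an operation's inputs are inconsistent."""


class ConfigurationError(ValueError):
    """Raised for invalid preprocessing / analysis configurations."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochWindow:
    """A half-open time window [t_start, t_end) relative to probe onset."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"EpochWindow {self.label!r}: t_start={self.t_start} must be "
                f"< t_end={self.t_end}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


#: Canonical task epochs.
FIXATION = EpochWindow("fixation", -6.0, -5.0)
ENCODING = EpochWindow("encoding", -5.0, -3.0)
MAINTENANCE = EpochWindow("maintenance", -3.0, 0.0)
#: Last 2 s of the delay; the analysis window for maintenance-period effects.
MAINTENANCE_ANALYSIS = EpochWindow("maintenance", -2.0, 0.0)

GRID_COLUMNS = "ABCDEFGH"
GRID_ROWS = tuple(range(1, 9))

CHANNEL_ROLES = ("hippocampal_lfp", "ecog_grid", "ecog_strip", "scalp")


@dataclass(frozen=True)
class ChannelInfo:
    name: str
    role: str
    grid_pos: tuple[str, int] | None = None  # (column 'A'..'H', row 1..8)
    hemisphere: str = "none"

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValidationError(f"unknown channel role {self.role!r}")
        if (self.role == "ecog_grid") != (self.grid_pos is not None):
            raise ValidationError(
                f"channel {self.name!r}: grid_pos must be present iff "
                "role == 'ecog_grid'"
            )
        if self.grid_pos is not None:
            col, row = self.grid_pos
            if col not in GRID_COLUMNS or row not in GRID_ROWS:
                raise ValidationError(
                    f"channel {self.name!r}: grid_pos {self.grid_pos!r} "
                    "outside the 8x8 grid (columns A-H, rows 1-8)"
                )
        if self.hemisphere not in ("left", "right", "none"):
            raise ValidationError(f"bad hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class TrialInfo:
    set_size: int
    correct: bool
    probe_in: bool
    rt: float  # seconds

    def __post_init__(self) -> None:
        if self.set_size not in (4, 6, 8):
            raise ValidationError(f"set_size must be 4, 6 or 8, got {self.set_size}")
        if self.rt is not None and not self.rt > 0:
            raise ValidationError(f"rt must be > 0, got {self.rt}")


@dataclass
class TrialSet:
    """Epoched trials: data[n_trials, n_channels, n_samples] in microvolts."""

    data: np.ndarray
    fs: float
    t0_offset: float  # time of the first sample, s relative to probe onset
    channels: list[ChannelInfo]
    trials: list[TrialInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-d (trials, channels, samples), got shape "
                f"{self.data.shape}"
            )
        n_trials, n_channels, _ = self.data.shape
        if len(self.channels) != n_channels:
            raise ValidationError(
                f"{len(self.channels)} ChannelInfo entries for {n_channels} "
                "data channels"
            )
        if len(self.trials) != n_trials:
            raise ValidationError(
                f"{len(self.trials)} TrialInfo entries for {n_trials} trials"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if np.isnan(self.data).any():
            raise ValidationError("data contains NaNs")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def window_slice(self, window: EpochWindow) -> slice:
        """Sample slice for the half-open window [t_start, t_end)."""
        t = self.times
        start = int(np.searchsorted(t, window.t_start - 1e-9, side="left"))
        stop = int(np.searchsorted(t, window.t_end - 1e-9, side="left"))
        if start >= stop:
            raise ValidationError(
                f"window [{window.t_start}, {window.t_end}) contains no samples "
                f"(trial spans [{t[0]:.3f}, {t[-1] + 1 / self.fs:.3f}))"
            )
        return slice(start, stop)

    def extract(self, window: EpochWindow) -> "TrialSet":
        """New TrialSet restricted to an epoch window."""
        sl = self.window_slice(window)
        return TrialSet(
            data=self.data[:, :, sl].copy(),
            fs=self.fs,
            t0_offset=float(self.times[sl.start]),
            channels=list(self.channels),
            trials=list(self.trials),
        )

    def pick_channels(self, names: Sequence[str]) -> "TrialSet":
        idx = [self.channel_index(n) for n in names]
        return TrialSet(
            data=self.data[:, idx, :].copy(),
            fs=self.fs,
            t0_offset=self.t0_offset,
            channels=[self.channels[i] for i in idx],
            trials=list(self.trials),
        )


# --------------------------------------------------------------------------
# re-referencing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceScheme:
    """Maps channel roles to their reference channels.

    Each listed role is re-referenced against the mean of its reference
    channels (a single channel for depth-electrode references, the two
    mastoids for scalp EEG).  Depth LFP and cortical ECoG must use distinct
    reference channels: a shared reference injects a common signal into both
    groups and produces spurious coupling estimates.
    """

    references: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for role, refs in self.references.items():
            if role not in CHANNEL_ROLES:
                raise ConfigurationError(f"unknown role {role!r} in scheme")
            if len(refs) == 0:
                raise ConfigurationError(f"role {role!r} has no reference channels")
        lfp_refs = set(self.references.get("hippocampal_lfp", ()))
        ecog_refs = set(self.references.get("ecog_grid", ())) | set(
            self.references.get("ecog_strip", ())
        )
        shared = lfp_refs & ecog_refs
        if shared:
            raise ConfigurationError(
                f"LFP and ECoG share reference channel(s) {sorted(shared)}; "
                "the two groups require distinct references"
            )


def rereference(ts: TrialSet, scheme: ReferenceScheme) -> TrialSet:
    """Subtract each group's reference signal; drop the reference channels."""
    all_refs: set[str] = set()
    for refs in scheme.references.values():
        all_refs.update(refs)
    for name in all_refs:
        ts.channel_index(name)  # raises KeyError if missing

    out = ts.data.copy()
    for role, refs in scheme.references.items():
        ref_idx = [ts.channel_index(r) for r in refs]
        ref_sig = ts.data[:, ref_idx, :].mean(axis=1, keepdims=True)
        ch_idx = [
            i
            for i, c in enumerate(ts.channels)
            if c.role == role and c.name not in all_refs
        ]
        if ch_idx:
            out[:, ch_idx, :] -= ref_sig
    keep = [i for i, c in enumerate(ts.channels) if c.name not in all_refs]
    if not keep:
        raise ValidationError("re-referencing would drop every channel")
    return TrialSet(
        data=out[:, keep, :],
        fs=ts.fs,
        t0_offset=ts.t0_offset,
        channels=[ts.channels[i] for i in keep],
        trials=list(ts.trials),
    )


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def _resample_filter(up: int, down: int, fs: float) -> np.ndarray:
    """Anti-alias FIR for polyphase resampling.

    Linear-phase Kaiser FIR, cutoff 0.8x the new Nyquist, >= 70 dB stopband
    attenuation at the new Nyquist; `resample_poly` compensates the group
    delay so the overall operation is zero phase (phase preservation matters
    for phase-locking and Granger estimates downstream).
    """
    fs_up = fs * up
    new_nyq = fs * up / down / 2.0
    cutoff = 0.8 * new_nyq
    width = new_nyq - cutoff
    numtaps, beta = signal.kaiserord(70.0, width / (fs_up / 2.0))
    numtaps |= 1  # odd length -> integer group delay, exact type-I symmetry
    # resample_poly scales the supplied coefficients by `up` itself
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_up)


def downsample(ts: TrialSet, target_fs: float) -> TrialSet:
    """Resample to ``target_fs`` with anti-alias filtering.

    The resampling ratio must be rational (it is derived from the float
    rates with a tolerance of 1e-6).
    """
    if target_fs > ts.fs:
        raise ConfigurationError(
            f"target_fs={target_fs} exceeds current fs={ts.fs}"
        )
    if target_fs == ts.fs:
        return ts
    from fractions import Fraction

    ratio = Fraction(target_fs / ts.fs).limit_denominator(10_000)
    if abs(float(ratio) - target_fs / ts.fs) > 1e-6:
        raise ConfigurationError(
            f"resampling ratio {target_fs}/{ts.fs} is not rational"
        )
    up, down = ratio.numerator, ratio.denominator
    h = _resample_filter(up, down, ts.fs)
    out = signal.resample_poly(
        ts.data, up, down, axis=-1, window=h, padtype="reflect"
    )
    return TrialSet(
        data=out,
        fs=target_fs,
        t0_offset=ts.t0_offset,
        channels=list(ts.channels),
        trials=list(ts.trials),
    )


# --------------------------------------------------------------------------
# artifact rejection and trial selection
# --------------------------------------------------------------------------

def reject_artifacts(
    ts: TrialSet,
    amp_threshold: float = 500.0,
    z_threshold: float = 6.0,
) -> tuple[TrialSet, np.ndarray]:
    """Drop trials with large unitary artifacts.

    A trial is rejected when, on any channel, its peak absolute amplitude
    exceeds ``amp_threshold`` (microvolts) or its peak robust z-score exceeds
    ``z_threshold``.  The robust z uses the per-channel median and scaled MAD
    pooled over all trials, so a single spiking trial cannot inflate its own
    baseline.  Returns the surviving TrialSet and the rejected trial indices.
    """
    if not amp_threshold > 0 or not z_threshold > 0:
        raise ConfigurationError("thresholds must be > 0")
    x = ts.data  # (trials, channels, samples)
    peak_amp = np.abs(x).max(axis=2).max(axis=1)
    med = np.median(x, axis=(0, 2), keepdims=True)
    mad = np.median(np.abs(x - med), axis=(0, 2), keepdims=True)
    scale = 1.4826 * mad
    scale = np.where(scale > 0, scale, np.inf)
    peak_z = (np.abs(x - med) / scale).max(axis=2).max(axis=1)
    bad = (peak_amp > amp_threshold) | (peak_z > z_threshold)
    rejected = np.flatnonzero(bad)
    if bad.all():
        raise ValidationError("artifact rejection removed every trial")
    keep = np.flatnonzero(~bad)
    out = TrialSet(
        data=x[keep].copy(),
        fs=ts.fs,
        t0_offset=ts.t0_offset,
        channels=list(ts.channels),
        trials=[ts.trials[i] for i in keep],
    )
    return out, rejected


def select_trials(
    ts: TrialSet,
    set_sizes: Iterable[int] | None = None,
    correct: bool | None = None,
) -> TrialSet:
    """Filter trials by set size and/or correctness, metadata preserved."""
    sizes = None if set_sizes is None else set(set_sizes)
    keep = [
        i
        for i, tr in enumerate(ts.trials)
        if (sizes is None or tr.set_size in sizes)
        and (correct is None or tr.correct == correct)
    ]
    if not keep:
        raise ValidationError(
            f"no trials match set_sizes={sizes} correct={correct}"
        )
    return TrialSet(
        data=ts.data[keep].copy(),
        fs=ts.fs,
        t0_offset=ts.t0_offset,
        channels=list(ts.channels),
        trials=[ts.trials[i] for i in keep],
    )
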
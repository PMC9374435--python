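"""Multitaper spectral estimation.

Per-trial, per-taper complex Fourier coefficients are the shared primitive:
phase locking uses their normalized cross-terms and Granger causality uses
their averaged outer products.  Tapers are normalized to unit energy, so the
(two-sided) spectral density of a channel is ``|X(f)|**2 / fs`` and a
one-sided density is twice that for 0 < f < Nyquist.

Taper families
--------------
``dpss``
    Slepian tapers; the time-bandwidth product defaults to ``(K + 1) / 2``
    for ``K`` tapers so that all requested tapers are well concentrated.
``hann``
    Sine tapers (Riedel-Sidorenko).  The first sine taper applies a Hann
    window in power, and higher orders form the orthogonal family that a
    "multiple Hann taper" estimate requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .data import ConfigurationError, EpochWindow, TrialSet, ValidationError


def sine_tapers(n: int, k: int) -> np.ndarray:
    """First ``k`` sine tapers of length ``n`` (unit energy, orthonormal)."""
    t = np.arange(1, n + 1)
    tapers = np.sin(np.pi * np.outer(np.arange(1, k + 1), t) / (n + 1))
    return tapers * np.sqrt(2.0 / (n + 1))


def make_tapers(n: int, n_tapers: int, family: str, nw: float | None = None) -> np.ndarray:
    if n_tapers < 1:
        raise ConfigurationError("n_tapers must be >= 1")
    if family == "dpss":
        if nw is None:
            nw = (n_tapers + 1) / 2.0
        return windows.dpss(n, nw, Kmax=n_tapers, norm=2)
    if family == "hann":
        return sine_tapers(n, n_tapers)
    raise ConfigurationError(f"unknown taper family {family!r}")


@dataclass
class SpectralCoefficients:
    """Tapered Fourier coefficients [n_trials x n_tapers x n_channels x n_freqs]."""

    coeffs: np.ndarray
    freqs: np.ndarray
    fs: float
    window: EpochWindow
    channel_names: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_tapers(self) -> int:
        return self.coeffs.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None


def multitaper_coeffs(
    ts: TrialSet,
    window: EpochWindow,
    freqs: np.ndarray | str = "full",
    n_tapers: int = 2,
    taper_family: str = "dpss",
    padding_s: float | None = None,
    nw: float | None = None,
    demean: bool = True,
) -> SpectralCoefficients:
    """Tapered Fourier coefficients of one epoch window.

    Zero padding to ``padding_s`` sets the frequency grid spacing to
    ``1 / padding_s``; requested frequencies are snapped to that grid.
    ``freqs="full"`` returns the whole one-sided grid from 0 to Nyquist
    (required by spectral matrix factorization).
    """
    seg = ts.data[:, :, ts.window_slice(window)]
    n = seg.shape[-1]
    if padding_s is None:
        nfft = n
    else:
        if padding_s * ts.fs < n - 0.5:
            raise ConfigurationError(
                f"padding_s={padding_s} shorter than the {n / ts.fs:.3f} s window"
            )
        nfft = int(round(padding_s * ts.fs))
    if demean:
        seg = seg - seg.mean(axis=-1, keepdims=True)
    tapers = make_tapers(n, n_tapers, taper_family, nw=nw)
    # (trials, channels, n) x (tapers, n) -> (trials, tapers, channels, nfft)
    tapered = seg[:, None, :, :] * tapers[None, :, None, :]
    grid = np.fft.rfftfreq(nfft, 1.0 / ts.fs)
    coeffs = np.fft.rfft(tapered, n=nfft, axis=-1)
    if isinstance(freqs, str):
        if freqs != "full":
            raise ConfigurationError(f"freqs must be an array or 'full', got {freqs!r}")
        sel = np.arange(grid.size)
    else:
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        if np.any(freqs > ts.fs / 2 + 1e-9):
            raise ConfigurationError(
                f"requested frequency {freqs.max()} Hz above Nyquist {ts.fs / 2} Hz"
            )
        sel = np.unique(np.round(freqs * nfft / ts.fs).astype(int))
        sel = sel[sel < grid.size]
    return SpectralCoefficients(
        coeffs=coeffs[..., sel],
        freqs=grid[sel],
        fs=ts.fs,
        window=window,
        channel_names=ts.channel_names,
    )


# --------------------------------------------------------------------------
# time-frequency power
# --------------------------------------------------------------------------

@dataclass
class TimeFreqMap:
    """Power over channels x frequencies x times.

    ``kind`` is ``raw_power`` (one-sided density, uV^2/Hz), ``relative_change``
    ((P - baseline)/baseline, unitless, >= -1) or ``delta_granger``.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: str
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.kind == "raw_power" and np.any(self.values < 0):
            raise ValidationError("raw power map has negative entries")
        if self.kind == "relative_change" and np.any(self.values < -1):
            raise ValidationError("relative change below -1")


def tf_psd(
    ts: TrialSet,
    freqs: np.ndarray | None = None,
    time_step: float = 0.1,
    cycles_per_window: float = 10.0,
    smoothing_factor: float = 0.2,
    n_tapers: int = 3,
) -> TimeFreqMap:
    """Trial-averaged multitaper time-frequency power.

    Frequency-adaptive windows: at frequency f the window spans
    ``cycles_per_window / f`` seconds and is tapered with DPSS of spectral
    half-bandwidth ``smoothing_factor * f`` (time-bandwidth product
    ``cycles_per_window * smoothing_factor``, 2.0 at the defaults, which
    admits the default 3 tapers).  Frequencies whose window does not fit in
    the trial are dropped with a warning.
    """
    if freqs is None:
        freqs = np.arange(4.0, 101.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs > ts.fs / 2):
        raise ConfigurationError("frequency above Nyquist")
    t = ts.times
    span = ts.n_samples / ts.fs
    keep, dropped = [], []
    for f in freqs:
        if cycles_per_window / f <= span:
            keep.append(f)
        else:
            dropped.append(f)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} frequencies whose {cycles_per_window}-cycle "
            f"window exceeds the {span:.2f} s trial span (lowest kept: "
            f"{keep[0] if keep else None} Hz)"
        )
    if not keep:
        raise ConfigurationError("no analyzable frequencies")
    freqs = np.asarray(keep)

    # time grid over the full trial span; windows whose half-length exceeds
    # the distance to a trial edge are shifted inward (nominal centre kept)
    times = np.arange(np.ceil(t[0] / time_step), np.floor(t[-1] / time_step) + 0.5)
    times = times * time_step
    if times.size == 0:
        raise ConfigurationError("trial too short for the requested windows")

    n_trials, n_channels, _ = ts.data.shape
    values = np.empty((n_channels, freqs.size, times.size))
    for fi, f in enumerate(freqs):
        n_win = int(round(cycles_per_window / f * ts.fs))
        n_win = min(n_win, ts.n_samples)
        nw = smoothing_factor * f * (n_win / ts.fs)
        k = min(n_tapers, max(1, int(np.floor(2 * nw - 1))))
        tapers = windows.dpss(n_win, max(nw, (k + 1) / 2.0), Kmax=k, norm=2)
        t_rel = (np.arange(n_win) - (n_win - 1) / 2) / ts.fs
        kernel = tapers * np.exp(-2j * np.pi * f * t_rel)  # (k, n_win)
        centers = np.round((times - t[0]) * ts.fs).astype(int)
        starts = centers - n_win // 2
        starts = np.clip(starts, 0, ts.n_samples - n_win)
        segs = np.stack(
            [ts.data[:, :, s : s + n_win] for s in starts], axis=2
        )  # (trials, channels, times, n_win)
        segs = segs - segs.mean(axis=-1, keepdims=True)
        x = np.tensordot(segs, kernel, axes=([3], [1]))  # -> (tr, ch, times, k)
        power = (np.abs(x) ** 2).mean(axis=(0, 3)) * (2.0 / ts.fs)
        values[:, fi, :] = power
    return TimeFreqMap(
        values=values,
        freqs=freqs,
        times=times,
        kind="raw_power",
        channel_names=ts.channel_names,
    )


def relative_change(tfmap: TimeFreqMap, baseline: EpochWindow) -> TimeFreqMap:
    """Baseline-corrected power: (P(t,f) - mean_base P(f)) / mean_base P(f)."""
    if tfmap.kind != "raw_power":
        raise ValidationError(f"expected a raw_power map, got kind={tfmap.kind!r}")
    in_base = (tfmap.times >= baseline.t_start) & (tfmap.times < baseline.t_end)
    if not in_base.any():
        raise ValidationError(
            f"baseline [{baseline.t_start}, {baseline.t_end}) has no time bins"
        )
    base = tfmap.values[:, :, in_base].mean(axis=2, keepdims=True)
    zero = np.isclose(base[..., 0], 0)
    if zero.any():
        ch, fi = np.argwhere(zero)[0]
        raise ValidationError(
            f"zero baseline power at {tfmap.freqs[fi]:.2f} Hz "
            f"(channel {tfmap.channel_names[ch]!r})"
        )
    return TimeFreqMap(
        values=(tfmap.values - base) / base,
        freqs=tfmap.freqs,
        times=tfmap.times,
        kind="relative_change",
        channel_names=list(tfmap.channel_names),
    )
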
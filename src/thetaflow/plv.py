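"""Phase-locking value between channel pairs.

For channels i, j with tapered Fourier coefficients X_i(f), X_j(f),

    PLV_{i,j}(f) = | (1/N) sum_n  X_i(f) X_j(f)* / (|X_i(f)| |X_j(f)|) |,

the resultant length of the per-trial phase differences over the N trials.
PLV is 1 when the two signals keep a constant phase relationship across
trials and tends to 0 for independent phases (with the well-known positive
small-sample bias E[PLV] ~ sqrt(pi)/2 * N^(-1/2) under independence, which
is why N is carried alongside the values).

Taper handling: the normalized cross-terms are averaged across tapers
within each trial before the across-trial resultant is taken, so N in the
formula is the trial count.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .data import ChannelInfo, ConfigurationError, EpochWindow, TrialSet, ValidationError
from .spectral import SpectralCoefficients, multitaper_coeffs
from .stats import GRID_SHAPE, GridMap


@dataclass
class PLVSpectrum:
    values: np.ndarray  # (n_pairs, n_freqs) in [0, 1]
    freqs: np.ndarray
    window: EpochWindow
    n_trials: int
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise ValidationError("PLV values outside [0, 1]")

    def pair_index(self, pair: tuple[str, str]) -> int:
        if pair in self.pairs:
            return self.pairs.index(pair)
        rev = (pair[1], pair[0])
        if rev in self.pairs:
            return self.pairs.index(rev)
        raise KeyError(f"pair {pair} not in spectrum")


def plv_spectrum(
    coeffs: SpectralCoefficients, pairs: list[tuple[str, str]]
) -> PLVSpectrum:
    """PLV for each channel pair from tapered Fourier coefficients."""
    if coeffs.n_trials < 1:
        raise ValidationError("PLV requires at least one trial")
    x = coeffs.coeffs
    mag = np.abs(x)
    if np.any(mag == 0):
        n, t, c, f = np.argwhere(mag == 0)[0]
        raise ValidationError(
            f"zero-magnitude coefficient (trial {n}, taper {t}, channel "
            f"{coeffs.channel_names[c]!r}, {coeffs.freqs[f]:.2f} Hz); "
            "PLV undefined for an exactly zero signal"
        )
    unit = x / mag
    values = np.empty((len(pairs), coeffs.freqs.size))
    for k, (a, b) in enumerate(pairs):
        i, j = coeffs.channel_index(a), coeffs.channel_index(b)
        cross = unit[:, :, i, :] * np.conj(unit[:, :, j, :])  # (trials, tapers, f)
        values[k] = np.abs(cross.mean(axis=1).mean(axis=0))
    return PLVSpectrum(
        values=values,
        freqs=coeffs.freqs,
        window=coeffs.window,
        n_trials=coeffs.n_trials,
        pairs=list(pairs),
    )


def plv_pairs(
    ts: TrialSet,
    pairs: list[tuple[str, str]],
    window: EpochWindow,
    freqs: np.ndarray | None = None,
    n_tapers: int = 2,
    taper_family: str = "dpss",
) -> PLVSpectrum:
    """Convenience wrapper: coefficients + PLV in one call.

    Defaults follow the study configuration: 2 tapers, [4 100] Hz at 1 Hz
    resolution.
    """
    if freqs is None:
        freqs = np.arange(4.0, min(100.0, ts.fs / 2) + 0.5, 1.0)
    padding = max(1.0, window.duration)  # >= 1 s padding -> <= 1 Hz spacing
    coeffs = multitaper_coeffs(
        ts, window, freqs=freqs, n_tapers=n_tapers,
        taper_family=taper_family, padding_s=padding,
    )
    return plv_spectrum(coeffs, pairs)


def plv_grid_map(
    plv: PLVSpectrum,
    band: tuple[float, float],
    reference_channel: str,
    channels: list[ChannelInfo],
) -> GridMap:
    """Band-averaged PLV of every grid contact to the reference channel."""
    lo, hi = band
    sel = (plv.freqs >= lo - 1e-9) & (plv.freqs <= hi + 1e-9)
    if not sel.any():
        raise ConfigurationError(f"band {band} outside the PLV frequency grid")
    values = np.full(GRID_SHAPE, np.nan)
    by_name = {c.name: c for c in channels}
    for k, (a, b) in enumerate(plv.pairs):
        other = b if a == reference_channel else a if b == reference_channel else None
        if other is None:
            continue
        info = by_name.get(other)
        if info is None or info.grid_pos is None:
            warnings.warn(f"channel {other!r} has no grid position; excluded")
            continue
        col, row = info.grid_pos
        values["ABCDEFGH".index(col), row - 1] = plv.values[k, sel].mean()
    if np.isnan(values).all():
        raise ValidationError("no grid contacts found among the PLV pairs")
    return GridMap(values=values, measure="plv", band=band, window=plv.window)
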
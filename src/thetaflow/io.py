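"""File I/O for TrialSets.

Two formats are supported:

* **fixture** — the package's native container: ``<name>.dat`` holding the
  raw samples as little-endian float32 in trial-major order, next to
  ``<name>.json`` with the sampling rate, epoch offset and full channel /
  trial metadata.  Round trips are bit-exact for float32 data.
* **edf** — plain European Data Format for interchange with clinical
  viewers.  Trials are written as consecutive fixed-length data records
  (one record per trial); amplitudes are quantized to the 16-bit EDF sample
  grid.  A ``<name>.json`` sidecar keeps the trial metadata that EDF cannot
  carry.  Reading uses MNE's EDF reader, which doubles as an independent
  check on the writer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import ChannelInfo, TrialInfo, TrialSet, ValidationError

_FORMATS = ("fixture", "edf")


def _meta_dict(ts: TrialSet) -> dict:
    return {
        "fs": ts.fs,
        "t0_offset": ts.t0_offset,
        "n_trials": ts.n_trials,
        "n_channels": ts.n_channels,
        "n_samples": ts.n_samples,
        "channels": [
            {
                "name": c.name,
                "role": c.role,
                "grid_pos": list(c.grid_pos) if c.grid_pos else None,
                "hemisphere": c.hemisphere,
            }
            for c in ts.channels
        ],
        "trials": [
            {
                "set_size": t.set_size,
                "correct": t.correct,
                "probe_in": t.probe_in,
                "rt": t.rt,
            }
            for t in ts.trials
        ],
    }


def _meta_from_dict(meta: dict) -> tuple[list[ChannelInfo], list[TrialInfo]]:
    channels = [
        ChannelInfo(
            name=c["name"],
            role=c["role"],
            grid_pos=tuple(c["grid_pos"]) if c.get("grid_pos") else None,
            hemisphere=c.get("hemisphere", "none"),
        )
        for c in meta["channels"]
    ]
    trials = [
        TrialInfo(
            set_size=t["set_size"],
            correct=t["correct"],
            probe_in=t["probe_in"],
            rt=t["rt"],
        )
        for t in meta["trials"]
    ]
    return channels, trials


def save_trials(ts: TrialSet, path: str | Path, format: str = "fixture") -> Path:
    """Write a TrialSet; returns the path of the primary file."""
    if format not in _FORMATS:
        raise ValidationError(f"unknown format {format!r}; expected {_FORMATS}")
    if ts.n_trials == 0:
        raise ValidationError("refusing to save an empty trial list")
    path = Path(path)
    if format == "fixture":
        base = path.with_suffix("") if path.suffix == ".dat" else path
        data32 = ts.data.astype("<f4")
        data32.tofile(base.with_suffix(".dat"))
        base.with_suffix(".json").write_text(json.dumps(_meta_dict(ts), indent=1))
        return base.with_suffix(".dat")
    base = path.with_suffix("") if path.suffix == ".edf" else path
    _write_edf(ts, base.with_suffix(".edf"))
    base.with_suffix(".json").write_text(json.dumps(_meta_dict(ts), indent=1))
    return base.with_suffix(".edf")


def load_trials(path: str | Path, format: str = "fixture") -> TrialSet:
    """Read a TrialSet written by :func:`save_trials`."""
    if format not in _FORMATS:
        raise ValidationError(f"unknown format {format!r}; expected {_FORMATS}")
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".dat", ".edf", ".json") else path
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"metadata sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    channels, trials = _meta_from_dict(meta)
    shape = (meta["n_trials"], meta["n_channels"], meta["n_samples"])
    if format == "fixture":
        raw = np.fromfile(base.with_suffix(".dat"), dtype="<f4")
        if raw.size != int(np.prod(shape)):
            raise ValidationError(
                f"{base.with_suffix('.dat')}: {raw.size} samples on disk, "
                f"metadata promises {shape}"
            )
        data = raw.reshape(shape).astype(float)
    else:
        data = _read_edf(base.with_suffix(".edf"), shape)
    return TrialSet(
        data=data,
        fs=meta["fs"],
        t0_offset=meta["t0_offset"],
        channels=channels,
        trials=trials,
    )


# --------------------------------------------------------------------------
# minimal EDF writer (plain EDF, one data record per trial)
# --------------------------------------------------------------------------

def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Physical min/max in <= 8 ASCII chars."""
    for fmt in ("{:.6g}", "{:.4g}", "{:.2g}"):
        s = fmt.format(v)
        if len(s) <= 8:
            return s
    return "{:.1e}".format(v)


def edf_quantization_step(ts: TrialSet) -> float:
    """Amplitude resolution (uV per digital unit) of the EDF export."""
    lo, hi = _edf_phys_range(ts)
    return (hi - lo) / (32767 - (-32768))


def _edf_phys_range(ts: TrialSet) -> tuple[float, float]:
    amax = float(np.abs(ts.data).max())
    amax = max(amax, 1e-6)
    return -amax, amax


def _write_edf(ts: TrialSet, path: Path) -> None:
    n_sig = ts.n_channels
    n_rec = ts.n_trials
    spr = ts.n_samples  # samples per record per signal
    rec_dur = spr / ts.fs
    lo, hi = _edf_phys_range(ts)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate X X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(256 * (1 + n_sig)), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_rec), 8),
            _ascii_field(_fmt_phys(rec_dur), 8),
            _ascii_field(str(n_sig), 4),
        ]
    )
    labels = [c.name for c in ts.channels]
    per_sig = b"".join(
        [
            b"".join(_ascii_field(lab, 16) for lab in labels),
            b"".join(_ascii_field("", 80) for _ in labels),
            b"".join(_ascii_field("uV", 8) for _ in labels),
            b"".join(_ascii_field(_fmt_phys(lo), 8) for _ in labels),
            b"".join(_ascii_field(_fmt_phys(hi), 8) for _ in labels),
            b"".join(_ascii_field(str(dig_min), 8) for _ in labels),
            b"".join(_ascii_field(str(dig_max), 8) for _ in labels),
            b"".join(_ascii_field("", 80) for _ in labels),
            b"".join(_ascii_field(str(spr), 8) for _ in labels),
            b"".join(_ascii_field("", 32) for _ in labels),
        ]
    )
    # reparse the (possibly rounded) printed physical range so that the
    # quantization used for writing matches what a reader reconstructs
    lo_r, hi_r = float(_fmt_phys(lo)), float(_fmt_phys(hi))
    gain = (hi_r - lo_r) / (dig_max - dig_min)
    digital = np.round((ts.data - lo_r) / gain + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(per_sig)
        # records: per trial, channel-major blocks
        digital.tofile(f)


def _read_edf(path: Path, shape: tuple[int, int, int]) -> np.ndarray:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; stored unit is uV
    n_trials, n_channels, n_samples = shape
    if data.shape[0] != n_channels or data.shape[1] < n_trials * n_samples:
        raise ValidationError(
            f"EDF stream shape {data.shape} inconsistent with metadata {shape}"
        )
    data = data[:, : n_trials * n_samples]
    return np.transpose(
        data.reshape(n_channels, n_trials, n_samples), (1, 0, 2)
    ).copy()
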
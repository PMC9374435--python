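#!/usr/bin/env python
"""Time-frequency power of a full-grid participant, baselined to fixation.

Verifies the epoch-locked oscillatory structure the generator plants:
gamma-band ([60 80] Hz) power on cortical contacts rises >100 % over the
fixation baseline during late encoding, and hippocampal beta ([12 24] Hz)
rises late in maintenance.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from thetaflow.data import FIXATION, select_trials
from thetaflow.simulate import SynthConfig, simulate_participant
from thetaflow.spectral import relative_change, tf_psd

BASE = Path(__file__).resolve().parent.parent / "results"


def band_time_mean(rc, channel, band, tspan):
    ci = rc.channel_names.index(channel)
    fsel = (rc.freqs >= band[0]) & (rc.freqs <= band[1])
    tsel = (rc.times >= tspan[0]) & (rc.times < tspan[1])
    return float(rc.values[ci][np.ix_(fsel, tsel)].mean())


def main() -> None:
    # a reduced full-column grid participant: focus column C plus neighbours
    subset = [(c, r) for c in "BCD" for r in range(1, 9)]
    cfg = SynthConfig(n_trials_per_participant=60, grid_subset=subset, seed=1)
    ts = select_trials(simulate_participant(cfg, 0), set_sizes={6, 8}, correct=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = tf_psd(ts, freqs=np.arange(4.0, 100.0, 2.0))
    rc = relative_change(raw, FIXATION)

    rows = []
    for ch in ["GRID_C2", "GRID_B5", "HIPP1"]:
        rows.append({
            "channel": ch,
            "gamma_60_80_late_encoding": band_time_mean(rc, ch, (60, 80), (-4, -3)),
            "gamma_60_80_fixation": band_time_mean(rc, ch, (60, 80), (-6, -5)),
            "beta_12_24_late_maintenance": band_time_mean(rc, ch, (12, 24), (-1, 0)),
        })
    table = pd.DataFrame(rows)
    BASE.mkdir(exist_ok=True)
    table.to_csv(BASE / "psd_bands.csv", index=False)
    print(table.round(3).to_string(index=False))
    g = table.loc[table.channel == "GRID_C2", "gamma_60_80_late_encoding"].iloc[0]
    b = table.loc[table.channel == "HIPP1", "beta_12_24_late_maintenance"].iloc[0]
    print(f"\ncortical gamma increase during late encoding: {100 * g:.0f} % "
          f"({'exceeds' if g > 1 else 'below'} the +100 % mark)")
    print(f"hippocampal beta increase late in maintenance: {100 * b:.0f} %")
    print(f"wrote {BASE / 'psd_bands.csv'}")


if __name__ == "__main__":
    main()
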
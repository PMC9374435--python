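#!/usr/bin/env python
"""Phase locking between hippocampus and the cortical grid.

Computes PLV spectra for the hippocampus-focus pair in fixation and
maintenance and a theta-band ([4 8] Hz) PLV grid map during the last two
seconds of maintenance; the map peaks at the coupling focus (C2),
mirroring how phase synchrony concentrates over auditory cortex in the
emulated recordings.

This demonstration uses a stronger maintenance coupling (gain 0.3) than
the Delta-Granger-calibrated default: a lagged linear coupling tuned to
|Delta-Granger| ~ 0.05 produces theta PLV increments of only ~0.05-0.1,
close to the Rayleigh bias floor at realistic trial counts, whereas real
recordings reach PLV ~ 0.4 at the focus (phase locking there is boosted by
common drive and volume conduction, which the generator deliberately
omits).  The stronger gain is the phase-locking-visible operating point
for exercising the map estimator.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thetaflow.data import FIXATION, MAINTENANCE_ANALYSIS, select_trials
from thetaflow.plv import plv_grid_map, plv_pairs
from thetaflow.simulate import SynthConfig, simulate_participant

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    subset = [(c, r) for c in "BCD" for r in range(1, 9)]
    cfg = SynthConfig(n_trials_per_participant=60, grid_subset=subset,
                      coupling_gain_maint=0.3, seed=1)
    ts = select_trials(simulate_participant(cfg, 0), set_sizes={6, 8}, correct=True)
    pairs = [("HIPP1", n) for n in ts.channel_names if n.startswith("GRID")]

    maint = plv_pairs(ts, pairs, MAINTENANCE_ANALYSIS)
    fix = plv_pairs(ts, pairs, FIXATION)
    focus = maint.pair_index(("HIPP1", "GRID_C2"))
    theta = (maint.freqs >= 4) & (maint.freqs <= 8)
    print(f"theta PLV hippocampus-C2: maintenance "
          f"{maint.values[focus, theta].mean():.3f} vs fixation "
          f"{fix.values[focus, (fix.freqs >= 4) & (fix.freqs <= 8)].mean():.3f} "
          f"(N={maint.n_trials} trials)")

    gm = plv_grid_map(maint, (4.0, 8.0), "HIPP1", ts.channels)
    col, row = gm.argmax_position()
    print(f"theta PLV grid map peaks at contact {col}{row} "
          f"(coupling focus: C2)")

    rows = [{"pair": f"HIPP1-{b}",
             "plv_theta_maintenance": float(maint.values[i, theta].mean()),
             "plv_theta_fixation": float(
                 fix.values[i, (fix.freqs >= 4) & (fix.freqs <= 8)].mean())}
            for i, (_, b) in enumerate(maint.pairs)]
    table = pd.DataFrame(rows)
    BASE.mkdir(exist_ok=True)
    table.to_csv(BASE / "plv_pairs.csv", index=False)
    print(f"wrote {BASE / 'plv_pairs.csv'}")


if __name__ == "__main__":
    main()
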
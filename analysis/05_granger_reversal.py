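#!/usr/bin/env python
"""The headline analysis: theta-band information flow and its reversal.

For every participant in the simulated dataset, computes nonparametric
spectral Granger causality between the cortical focus contact and the
hippocampal LFP in the encoding window ([-5, -3] s) and the maintenance
analysis window ([-2, 0] s), band-averages the net flow (Delta-Granger,
[4 8] Hz), and tests the encoding-vs-maintenance reversal across
participants with a paired permutation test.  A direction-swap permutation
null is run for the first participant, and the correct-trial effect is
re-estimated from balanced 10 % subsamples.  Writes a Table-1-like CSV.
"""

import json
from pathlib import Path

from thetaflow.data import ENCODING, select_trials
from thetaflow.io import load_trials
from thetaflow.pipeline import AnalysisConfig, run_full_analysis
from thetaflow.simulate import SynthConfig
from thetaflow.stats import direction_swap_null

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    manifest = json.loads((SCRATCH / "dataset" / "manifest.json").read_text())
    participants = [load_trials(f) for f in manifest["files"]]
    mc = manifest["config"]
    cfg = AnalysisConfig(
        synth=SynthConfig(
            n_participants=mc["n_participants"],
            n_trials_per_participant=mc["n_trials_per_participant"],
            grid_subset=[tuple(g) for g in mc["grid_subset"]],
            seed=mc["seed"],
        ),
        seed=1, out_dir=str(BASE / "granger"),
    )
    report = run_full_analysis(cfg, participants=participants)
    t = report.participants
    cols = ["participant", "enc_delta_granger_correct",
            "maint_delta_granger_correct", "enc_delta_granger_balanced",
            "maint_delta_granger_balanced", "enc_delta_granger_incorrect",
            "maint_delta_granger_incorrect"]
    print(t[cols].round(4).to_string(index=False))
    n_rev = int(((t.enc_delta_granger_correct < 0)
                 & (t.maint_delta_granger_correct > 0)).sum())
    print(f"\nreversal (encoding < 0 < maintenance): {n_rev}/{len(t)} participants")
    print(f"median Delta-Granger: encoding "
          f"{t.enc_delta_granger_correct.median():+.3f}, maintenance "
          f"{t.maint_delta_granger_correct.median():+.3f}")
    print(f"paired permutation test (correct trials): "
          f"p = {report.paired_test_correct.p:.4g} "
          f"(n_perm = {report.paired_test_correct.n_perm})")
    if report.paired_test_incorrect is not None:
        print(f"paired permutation test (incorrect trials): "
              f"p = {report.paired_test_incorrect.p:.4g} — no consistent reversal "
              f"expected (incorrect trials carry no directed coupling)")

    first = select_trials(participants[0], set_sizes={6, 8}, correct=True)
    res = direction_swap_null(first, cfg.focus_pair(), ENCODING,
                              n_perm=200, seed=5)
    print(f"\ndirection-swap null, participant 1, encoding: observed "
          f"Delta-Granger = {res.observed:+.4f}, p = {res.p:.4g} "
          f"(n_perm = {res.n_perm})")
    print(f"report + participants.csv written to {BASE / 'granger'}")


if __name__ == "__main__":
    main()
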
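#!/usr/bin/env python
"""Generate the synthetic study dataset and write it in the fixture format.

Produces one TrialSet per synthetic participant with the task's statistical
structure: theta oscillators on every channel, cortex->hippocampus lagged
coupling during encoding, the reverse during maintenance, epoch-locked
gamma/beta bursts, and behavioral labels.  For the pair-level connectivity
analyses only the hippocampal channel and the grid coupling focus (contact
C2) are simulated; script 03/04 regenerate a full-grid participant where
spatial maps are needed.
"""

import json
from dataclasses import asdict
from pathlib import Path

from thetaflow.io import save_trials
from thetaflow.simulate import SynthConfig, simulate_task_dataset

OUT = Path(__file__).resolve().parent.parent / "scratch" / "dataset"


def main() -> None:
    cfg = SynthConfig(n_participants=15, n_trials_per_participant=100,
                      grid_subset=[("C", 2)], seed=1)
    OUT.mkdir(parents=True, exist_ok=True)
    files = []
    for p, ts in enumerate(simulate_task_dataset(cfg)):
        files.append(str(save_trials(ts, OUT / f"participant_{p:02d}")))
        n_correct = sum(t.correct for t in ts.trials)
        print(f"participant {p:2d}: {ts.n_trials} trials "
              f"({n_correct} correct), {ts.n_channels} channels at {ts.fs} Hz")
    manifest = {"config": asdict(cfg), "files": files}
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    print(f"\nwrote {len(files)} participants + manifest to {OUT}")


if __name__ == "__main__":
    main()
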
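"""Behavioral summaries: accuracy, Cowan's K, reaction-time workload slope."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrialSet, ValidationError


@dataclass
class BehaviorSummary:
    accuracy_by_set_size: dict[int, float]
    cowans_k: float | None  # items; mean over set sizes present
    cowans_k_by_set_size: dict[int, float]
    mean_rt: float
    sd_rt: float
    rt_slope: float | None  # s per item; None when only one set size present
    n_correct: int
    n_incorrect: int


def cowans_k(correct_in_rate: float, correct_out_rate: float, set_size: int) -> float:
    """Working-memory capacity K = (IN rate + OUT rate - 1) x set size.

    May be negative at below-chance performance.
    """
    for r in (correct_in_rate, correct_out_rate):
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"rate {r} outside [0, 1]")
    return (correct_in_rate + correct_out_rate - 1.0) * set_size


def summarize_behavior(ts: TrialSet) -> BehaviorSummary:
    """Per-set-size accuracy, Cowan's K, and the RT workload slope.

    The RT slope is an ordinary least-squares fit of reaction time on set
    size over correct trials only (error-trial RTs are a separate
    population).  K is computed per set size from the correct-response
    rates of IN and OUT probes and averaged over the set sizes present.
    """
    trials = ts.trials
    sizes = sorted({t.set_size for t in trials})
    acc: dict[int, float] = {}
    k_by: dict[int, float] = {}
    for ss in sizes:
        sub = [t for t in trials if t.set_size == ss]
        acc[ss] = float(np.mean([t.correct for t in sub]))
        ins = [t.correct for t in sub if t.probe_in]
        outs = [t.correct for t in sub if not t.probe_in]
        if ins and outs:
            k_by[ss] = cowans_k(float(np.mean(ins)), float(np.mean(outs)), ss)
    correct = [t for t in trials if t.correct]
    n_correct = len(correct)
    rts = np.array([t.rt for t in correct])
    mean_rt = float(rts.mean()) if rts.size else float("nan")
    sd_rt = float(rts.std(ddof=1)) if rts.size > 1 else float("nan")
    rt_slope = None
    cs = np.array([t.set_size for t in correct], dtype=float)
    if np.unique(cs).size >= 2:
        rt_slope = float(np.polyfit(cs, rts, 1)[0])
    return BehaviorSummary(
        accuracy_by_set_size=acc,
        cowans_k=float(np.mean(list(k_by.values()))) if k_by else None,
        cowans_k_by_set_size=k_by,
        mean_rt=mean_rt,
        sd_rt=sd_rt,
        rt_slope=rt_slope,
        n_correct=n_correct,
        n_incorrect=len(trials) - n_correct,
    )
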
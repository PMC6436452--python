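"""Scoring of progressive-track responses and audiometric summaries.

The rapid test presents 20 trials per condition on a fixed descending TMR
schedule (+10 dB down to −8 dB, 2-dB steps, two trials per level).  The TMR
threshold is estimated as ten minus the number of correct responses, so a
perfect track scores −10 dB and a track with no correct responses scores
+10 dB.  The estimate depends only on the number correct, never on trial
order, and cannot leave [−10, +10].  The estimator is known to be most
accurate for true thresholds between −6 and +6 dB TMR and to underestimate
(report too-negative values for) listeners whose true thresholds are better
than −6 dB; no correction is applied here.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    PTA_HIGH_FREQS,
    PTA_STANDARD_FREQS,
    THRESHOLD_RANGE,
    Audiogram,
    ThresholdRecord,
    TrialBlock,
)

PTA_VARIANTS: dict[str, tuple[float, ...]] = {
    "standard": PTA_STANDARD_FREQS,
    "high_frequency": PTA_HIGH_FREQS,
}


def estimate_threshold(block: TrialBlock) -> int:
    """Score one 20-trial track: threshold (dB TMR) = 10 − number correct."""
    return 10 - int(np.count_nonzero(block.correct))


def compute_srm(colocated: float, separated: float) -> float:
    """Spatial release from masking: colocated minus separated threshold (dB)."""
    lo, hi = THRESHOLD_RANGE
    for name, t in (("colocated", colocated), ("separated", separated)):
        if not lo <= t <= hi:
            raise ValueError(f"{name} threshold {t} outside [{lo:g}, {hi:g}]")
    return colocated - separated


def average_runs(run1: float, run2: float) -> float:
    """Arithmetic mean of the run-1 and run-2 thresholds."""
    return (run1 + run2) / 2.0


def pta(audiogram: Audiogram, variant: str = "standard") -> float:
    """Bilateral pure-tone average (dB HL).

    ``standard`` averages 0.5/1/2/4 kHz over both ears; ``high_frequency``
    averages 1/2/4/8 kHz.  Unweighted mean of the eight thresholds.
    """
    try:
        freqs = PTA_VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown PTA variant {variant!r}") from None
    vals = []
    for ear_name, ear in (("left", audiogram.left), ("right", audiogram.right)):
        for f in freqs:
            if f not in ear:
                raise ValueError(f"{ear_name} ear missing {f} kHz required for {variant} PTA")
            vals.append(ear[f])
    return float(np.mean(vals))


def bilateral_asymmetry(audiogram: Audiogram) -> dict:
    """Interaural threshold differences |L − R| per frequency, with maxima.

    Returns ``per_freq`` (kHz -> dB), ``max`` over all matched frequencies,
    and ``max_below_2k`` restricted to frequencies below 2 kHz (the band the
    symmetry screen of the original cohort was applied to).
    """
    common = sorted(set(audiogram.left) & set(audiogram.right))
    per_freq = {f: abs(audiogram.left[f] - audiogram.right[f]) for f in common}
    below = [d for f, d in per_freq.items() if f < 2.0]
    return {
        "per_freq": per_freq,
        "max": max(per_freq.values()) if per_freq else 0.0,
        "max_below_2k": max(below) if below else 0.0,
    }


TRIAL_COLUMNS = ("id", "condition", "run", "trial", "tmr", "correct")


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Score a trial-level table into per-(participant, condition, run) thresholds.

    ``trials`` holds one row per trial with columns ``id, condition, run,
    trial, tmr, correct``.  Every (id, condition, run) group must form a
    complete 20-trial track.  Returns a tidy frame with one threshold row per
    track, ordered by id, condition, run.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table is missing columns: {missing}")
    out = []
    for (pid, cond, run), grp in trials.groupby(["id", "condition", "run"], sort=True):
        grp = grp.sort_values("trial")
        block = TrialBlock(
            condition=str(cond),
            schedule=tuple(int(t) for t in grp["tmr"]),
            correct=tuple(bool(c) for c in grp["correct"]),
        )
        rec = ThresholdRecord(
            condition=str(cond), run=str(run), tmr_threshold=estimate_threshold(block)
        )
        out.append(
            {"id": pid, "condition": rec.condition, "run": rec.run,
             "threshold": rec.tmr_threshold}
        )
    return pd.DataFrame(out, columns=["id", "condition", "run", "threshold"])


def audiogram_from_mapping(left: Mapping[float, float], right: Mapping[float, float]) -> Audiogram:
    """Build an :class:`Audiogram`, accepting any subset of the standard frequencies."""
    return Audiogram(left=dict(left), right=dict(right))


def synthesize_audiogram(pta_st: float) -> Audiogram:
    """Construct a symmetric flat-plus-sloping audiogram with a given standard PTA.

    The profile is flat through 1 kHz and rises linearly on a log-frequency
    axis above it (a presbycusis-like configuration).  The shape weights are
    chosen so the bilateral standard PTA equals ``pta_st`` exactly; the shape
    itself is cosmetic — only the PTA feeds the normative models.
    """
    if pta_st < 0:
        raise ValueError("target PTA must be nonnegative")
    # shape units per frequency; mean over (0.5, 1, 2, 4) is 0.5 units
    shape = {0.25: 0.0, 0.5: 0.0, 1.0: 0.0, 2.0: 0.5, 3.0: 1.0, 4.0: 1.5, 6.0: 2.2, 8.0: 3.0}
    unit = 0.6 * pta_st  # dB per shape unit -> base + 0.5*unit = pta_st
    base = pta_st - 0.5 * unit
    ear = {f: min(120.0, base + unit * s) for f, s in shape.items()}
    return Audiogram(left=ear, right=dict(ear))
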
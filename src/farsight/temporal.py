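"""Subjective time-perception metrics.

Two tasks probe whether risk groups differ in how they experience time:

* **Interval production (Volle)**: participants silently count to a target
  interval at a paced frequency (1 Hz blocks with 20/30/40/50 s targets,
  0.5 Hz blocks with 15/20/25/30 s targets).  Accuracy is the signed error
  ``produced - target``, averaged per block frequency (the two block means
  are analyzed separately).
* **Horizon estimation (Zauberman)**: participants rate how long future
  horizons (1 week to 10 years) feel on a bounded slider, with the 1-week
  horizon asked first as the anchor.  For each later horizon, objective
  growth is ``(T - T_anchor)/T_anchor`` and subjective growth the analogous
  slider quantity; their ratio is 1 when prospective time estimation is
  accurate, and the participant summary is the mean ratio over non-anchor
  trials.  The ratio is invariant to rescaling the slider, except for the
  degenerate zero-anchor response, which is flagged as undefined.

Calendar conversions: 1 week = 7 d, 1 month = 30 d, 1 year = 365 d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

VOLLE_TARGETS = {1.0: (20.0, 30.0, 40.0, 50.0), 0.5: (15.0, 20.0, 25.0, 30.0)}
ANCHOR_DAYS = 7


@dataclass(frozen=True)
class VolleTrial:
    block_hz: float        # pacing frequency: 1.0 or 0.5
    target_s: float
    produced_s: float | None  # elapsed time at the stop response; None = missed

    def __post_init__(self) -> None:
        if self.block_hz not in VOLLE_TARGETS:
            raise ValueError("block_hz must be 1.0 or 0.5")
        if self.target_s not in VOLLE_TARGETS[self.block_hz]:
            raise ValueError(
                f"target {self.target_s} not in the {self.block_hz} Hz menu "
                f"{VOLLE_TARGETS[self.block_hz]}"
            )


@dataclass(frozen=True)
class ZaubermanTrial:
    horizon_days: int
    slider: float

    def __post_init__(self) -> None:
        if self.horizon_days < ANCHOR_DAYS or self.horizon_days > 10 * 365:
            raise ValueError("horizon must lie between 1 week and 10 years")
        if self.slider < 0:
            raise ValueError("slider position must be non-negative")


@dataclass
class VolleAccuracy:
    mean_error_1hz: float
    mean_error_halfhz: float
    n_dropped: int


def volle_accuracy(trials) -> VolleAccuracy:
    """Per-block mean signed production error (seconds).

    Trials without a recorded keypress are dropped and counted.
    """
    errors = {1.0: [], 0.5: []}
    dropped = 0
    for t in trials:
        if t.produced_s is None or (isinstance(t.produced_s, float) and math.isnan(t.produced_s)):
            dropped += 1
            continue
        errors[t.block_hz].append(t.produced_s - t.target_s)
    for hz, errs in errors.items():
        if not errs:
            raise ValueError(f"no usable trials in the {hz} Hz block")
    return VolleAccuracy(
        mean_error_1hz=float(np.mean(errors[1.0])),
        mean_error_halfhz=float(np.mean(errors[0.5])),
        n_dropped=dropped,
    )


def zauberman_growth_ratio(trials) -> float:
    """Mean subjective/objective growth ratio across non-anchor horizons.

    Requires the 1-week anchor trial.  Returns NaN (undefined, to be
    flagged upstream) when the anchor slider response is 0.
    """
    trials = list(trials)
    anchors = [t for t in trials if t.horizon_days == ANCHOR_DAYS]
    if not anchors:
        raise ValueError("anchor (1 week) trial missing")
    anchor = anchors[0]
    rest = [t for t in trials if t.horizon_days > ANCHOR_DAYS]
    if not rest:
        raise ValueError("need at least one non-anchor trial")
    if anchor.slider == 0:
        return float("nan")
    ratios = []
    for t in rest:
        objective = (t.horizon_days - anchor.horizon_days) / anchor.horizon_days
        subjective = (t.slider - anchor.slider) / anchor.slider
        ratios.append(subjective / objective)
    return float(np.mean(ratios))
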
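"""Deterministic questionnaire scoring and data-quality exclusion rules.

Implements the published scoring keys for:

* **EAT-26** (eating-disorder risk screen, 26 items): items 1-25 coded
  Never/Rarely/Sometimes -> 0, Often -> 1, Usually -> 2, Always -> 3; item
  26 reverse-coded; total 0-78; totals **above 20** assign the "high risk"
  group.  A bulimia-free variant drops the binge/purge items 4, 9 and 25
  before summing and reapplies the same cutoff.
* **CFC** (Consideration of Future Consequences, 12 items, 1-5): items
  3-5 and 9-12 reverse-keyed; total 12-60.
* **ZTPI future subscale** (of the 56-item Zimbardo Time Perspective
  Inventory): mean of the 13 future items (9, 24 and 56 reverse-keyed).
* **PFE** (Preoccupation with Future Events): fraction of listed thoughts
  labeled "future".
* **BDI** (sum, 0-63), **STAI trait** (sum with reverse-keyed items,
  20-80) and **ATQ negative-affect** (item mean, 1-7) for the
  dispositional-negativity factor.

Exclusion rules: a participant is dropped from questionnaire analysis when
they completed < 75% of a used scale's items, or when a configured score
lies more than 3 SD from the sample mean (single pass, mean/SD taken from
the full pre-exclusion sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HIGH_RISK = "high"
LOW_RISK = "low"

EAT26_CUTOFF = 20  # totals strictly above this are high risk
EAT26_BULIMIA_ITEMS = (4, 9, 25)

# canonical 6-label frequency menu; the three low-frequency labels all code 0
EAT26_FORWARD_MAP = {
    "Never": 0, "Rarely": 0, "Sometimes": 0, "Often": 1, "Usually": 2, "Always": 3,
}
EAT26_REVERSE_MAP = {
    "Always": 0, "Usually": 0, "Often": 0, "Sometimes": 1, "Rarely": 2, "Never": 3,
}

CFC_REVERSED_ITEMS = frozenset({3, 4, 5, 9, 10, 11, 12})

# published future-subscale key of the 56-item ZTPI
ZTPI_FUTURE_ITEMS = (6, 9, 10, 13, 18, 21, 24, 30, 40, 43, 45, 51, 56)
ZTPI_FUTURE_REVERSED = frozenset({9, 24, 56})

# STAI trait form: anxiety-absent items are reverse-keyed (positions within
# the 20-item trait scale)
STAI_TRAIT_REVERSED = frozenset({1, 3, 6, 7, 10, 13, 14, 16, 19})


@dataclass(frozen=True)
class ScaleSpec:
    """Declarative description of a scale, shared with the response generator."""

    name: str
    n_items: int
    min_resp: int
    max_resp: int
    scoring: str               # "sum" or "mean"
    reversed_items: frozenset = frozenset()
    items: tuple = ()          # subscale item numbers; empty = all

    @property
    def used_items(self) -> tuple:
        return self.items if self.items else tuple(range(1, self.n_items + 1))

    def score_range(self) -> tuple[float, float]:
        n = len(self.used_items)
        if self.scoring == "sum":
            return n * self.min_resp, n * self.max_resp
        return float(self.min_resp), float(self.max_resp)


SCALES: dict[str, ScaleSpec] = {
    "cfc": ScaleSpec("cfc", 12, 1, 5, "sum", CFC_REVERSED_ITEMS),
    "ztpi_future": ScaleSpec("ztpi_future", 56, 1, 5, "mean",
                             ZTPI_FUTURE_REVERSED, ZTPI_FUTURE_ITEMS),
    "bdi": ScaleSpec("bdi", 21, 0, 3, "sum"),
    "stai": ScaleSpec("stai", 20, 1, 4, "sum", STAI_TRAIT_REVERSED),
    # ATQ short-form negative-affect subscale; reverse key configurable via
    # a replacement spec if a different instrument version is used
    "atq_na": ScaleSpec("atq_na", 26, 1, 7, "mean"),
}


def _as_item_map(items, n_items: int) -> dict[int, object]:
    if isinstance(items, Mapping):
        return dict(items)
    seq = list(items)
    if len(seq) != n_items:
        raise ValueError(f"expected {n_items} item responses, got {len(seq)}")
    return {i + 1: v for i, v in enumerate(seq)}


def score_eat26(
    items,
    exclude_bulimia: bool = False,
    label_map: Mapping[str, int] | None = None,
    reverse_label_map: Mapping[str, int] | None = None,
) -> tuple[int, str]:
    """Score the EAT-26 and return ``(total, risk_label)``.

    ``items`` maps item number (1-26) to a response label.  With
    ``exclude_bulimia`` the binge/purge items (4, 9, 25) are dropped before
    summing; the >20 cutoff is unchanged.
    """
    fwd = dict(label_map or EAT26_FORWARD_MAP)
    rev = dict(reverse_label_map or EAT26_REVERSE_MAP)
    resp = _as_item_map(items, 26)
    total = 0
    for item, label in resp.items():
        if not 1 <= item <= 26:
            raise ValueError(f"EAT-26 item number out of range: {item}")
        if exclude_bulimia and item in EAT26_BULIMIA_ITEMS:
            continue
        mapping = rev if item == 26 else fwd
        if label not in mapping:
            raise ValueError(f"unknown EAT-26 response label {label!r} (item {item})")
        total += mapping[label]
    return total, (HIGH_RISK if total > EAT26_CUTOFF else LOW_RISK)


def score_cfc(items) -> int:
    """Total CFC score (12-60); items 3-5 and 9-12 are reverse-keyed."""
    resp = _as_item_map(items, 12)
    if set(resp) != set(range(1, 13)):
        raise ValueError("CFC requires responses to items 1-12")
    total = 0
    for item, v in resp.items():
        v = int(v)
        if not 1 <= v <= 5:
            raise ValueError(f"CFC response out of range 1-5: {v} (item {item})")
        total += (6 - v) if item in CFC_REVERSED_ITEMS else v
    return total


def score_ztpi_future(items) -> float:
    """Mean of the ZTPI future-subscale items (1-5 scale, reverse-keyed
    items inverted).  Missing items (None/NaN) are ignored in the mean;
    completion accounting is handled by the exclusion rules.
    """
    if isinstance(items, Mapping):
        resp = dict(items)
    else:
        resp = _as_item_map(items, 56)
    vals = []
    for item in ZTPI_FUTURE_ITEMS:
        v = resp.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        v = int(v)
        if not 1 <= v <= 5:
            raise ValueError(f"ZTPI response out of range 1-5: {v} (item {item})")
        vals.append((6 - v) if item in ZTPI_FUTURE_REVERSED else v)
    if not vals:
        raise ValueError("all ZTPI future-subscale items missing")
    return float(np.mean(vals))


def score_pfe(thought_labels: Sequence[str]) -> float:
    """Ratio of future-directed thoughts to total thoughts listed (0-1)."""
    labels = list(thought_labels)
    if not labels:
        return float("nan")
    bad = set(labels) - {"past", "present", "future"}
    if bad:
        raise ValueError(f"unknown thought labels: {sorted(bad)}")
    return labels.count("future") / len(labels)


def _score_generic(spec: ScaleSpec, items) -> float:
    resp = _as_item_map(items, spec.n_items)
    vals = []
    for item in spec.used_items:
        v = resp.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        v = int(v)
        if not spec.min_resp <= v <= spec.max_resp:
            raise ValueError(
                f"{spec.name} response out of range "
                f"[{spec.min_resp}, {spec.max_resp}]: {v} (item {item})"
            )
        if item in spec.reversed_items:
            v = spec.min_resp + spec.max_resp - v
        vals.append(v)
    if not vals:
        raise ValueError(f"all {spec.name} items missing")
    return float(np.sum(vals)) if spec.scoring == "sum" else float(np.mean(vals))


def score_negativity_scales(bdi_items, stai_items, atq_na_items) -> tuple[float, float, float]:
    """Score the three dispositional-negativity indicators.

    Returns ``(bdi_total, stai_total, atq_na_mean)`` using the published
    keys: BDI sum (0-63), STAI trait sum with reverse-keyed items (20-80),
    ATQ negative-affect item mean (1-7).
    """
    return (
        _score_generic(SCALES["bdi"], bdi_items),
        _score_generic(SCALES["stai"], stai_items),
        _score_generic(SCALES["atq_na"], atq_na_items),
    )


def apply_quality_exclusions(
    scored: pd.DataFrame,
    completions: pd.DataFrame | None = None,
    outlier_fields: Iterable[str] = ("future_factor",),
    min_completion: float = 0.75,
    sd_limit: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the questionnaire-stream exclusion rules.

    ``scored`` has one row per participant (indexed or with a
    ``participant_id`` column).  ``completions`` gives per-scale completion
    fractions with matching rows.  Participants are excluded when any used
    scale's completion falls below ``min_completion``, or when any field in
    ``outlier_fields`` lies more than ``sd_limit`` SDs from the sample mean
    (mean/SD from the full pre-exclusion sample; single pass).

    Returns ``(retained, exclusion_log)``; the log has one row per
    (participant, reason).
    """
    df = scored.copy()
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    log_rows = []
    excluded = set()

    if completions is not None:
        comp = completions.copy()
        if "participant_id" in comp.columns:
            comp = comp.set_index("participant_id")
        for pid, row in comp.iterrows():
            for scale, frac in row.items():
                if pd.notna(frac) and frac < min_completion:
                    excluded.add(pid)
                    log_rows.append(
                        {"participant_id": pid, "scale": scale,
                         "reason": "insufficient responses", "value": float(frac)}
                    )

    for fieldname in outlier_fields:
        if fieldname not in df.columns:
            continue
        vals = df[fieldname].astype(float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (vals - mean) / sd
        for pid, zi in z.items():
            if pd.notna(zi) and abs(zi) > sd_limit:
                excluded.add(pid)
                log_rows.append(
                    {"participant_id": pid, "scale": fieldname,
                     "reason": "outlier", "value": float(zi)}
                )

    retained = df.loc[[p for p in df.index if p not in excluded]]
    log = pd.DataFrame(log_rows, columns=["participant_id", "scale", "reason", "value"])
    return retained, log
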
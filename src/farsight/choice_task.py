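"""Intertemporal-choice trial sets and catch trials.

Each trial offers a smaller-sooner (SS) and a larger-later (LL) hypothetical
monetary reward.  The generated set mirrors the published task design:
144 trials, SS amounts $15-$85, LL/SS relative differences of 2%-100%
(so LL amounts span $16-$170), SS delays of today / 2 weeks / 1 month and
LL delays of 1 week to 6 months, always later than the SS delay.  Catch
trials invert the trade-off (a *smaller later* vs. a *larger sooner*
reward) so that any LL choice on them indicates inattention.

The exact deposited trial table can be loaded verbatim with
:func:`load_trial_table`; :func:`build_choice_set` generates a seeded
approximation from the stated ranges, calibrated so that a noiseless
hyperbolic decision maker with log(k) near -5.3 splits the set roughly
evenly between SS and LL preferences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SS = "SS"
LL = "LL"

TRIAL_COLUMNS = [
    "trial_id",
    "ss_amount",
    "ss_delay_days",
    "ll_amount",
    "ll_delay_days",
    "is_catch",
    "side_ll",
]


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary intertemporal decision.

    Amounts are in USD, delays in integer days (0 = today).  For regular
    trials the later option is strictly larger; for catch trials it is
    strictly smaller (dominated), so the normatively correct response is SS.
    """

    trial_id: int
    ss_amount: float
    ll_amount: float
    ss_delay: int
    ll_delay: int
    is_catch: bool = False
    side_ll: str = "right"

    def __post_init__(self) -> None:
        if self.ss_delay < 0 or self.ll_delay < 0:
            raise ValueError("delays must be non-negative")
        if self.ll_delay <= self.ss_delay:
            raise ValueError("ll_delay must exceed ss_delay")
        if self.is_catch:
            if not self.ll_amount < self.ss_amount:
                raise ValueError("catch trials require a dominated (smaller) later option")
        elif not self.ll_amount > self.ss_amount:
            raise ValueError("non-catch trials require ll_amount > ss_amount")
        if self.side_ll not in ("left", "right"):
            raise ValueError("side_ll must be 'left' or 'right'")


@dataclass
class TaskDesign:
    """Parameters of the generated choice set.

    Calendar conversions: 1 week = 7 d, 2 weeks = 14 d, 1 month = 30 d,
    6 months = 180 d.
    """

    n_trials: int = 144
    ss_delay_menu: tuple[int, ...] = (0, 14, 30)
    ll_delay_range: tuple[int, int] = (7, 180)
    ss_amount_range: tuple[float, float] = (15.0, 85.0)
    ratio_range: tuple[float, float] = (0.02, 1.00)
    n_catch: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo_r, hi_r = self.ratio_range
        lo_a, hi_a = self.ss_amount_range
        if lo_r <= 0 or hi_r < lo_r:
            raise ValueError("ratio_range must be positive and ordered")
        if lo_a <= 0 or hi_a < lo_a:
            raise ValueError("ss_amount_range must be positive and ordered")
        if self.ll_delay_range[0] < 1 or self.ll_delay_range[1] < self.ll_delay_range[0]:
            raise ValueError("ll_delay_range must be ordered and >= 1 day")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if max(self.ss_delay_menu) >= self.ll_delay_range[1]:
            raise ValueError("ss delays must leave room for a later LL delay")


def _ceil_dollar(x: float) -> int:
    """LL amounts are rounded up to whole dollars ($15 x 1.02 -> $16)."""
    return int(math.ceil(x - 1e-9))


def indifference_log_k(trial: ChoiceTrial) -> float:
    """Natural-log hyperbolic discount rate at which SS and LL have equal value.

    Solves A_ss/(1+k t_ss) = A_ll/(1+k t_ll) for k.  Every generated
    non-catch trial admits a finite positive solution (the choice set is
    informative about k).
    """
    num = trial.ll_amount - trial.ss_amount
    den = trial.ss_amount * trial.ll_delay - trial.ll_amount * trial.ss_delay
    if den <= 0 or num <= 0:
        raise ValueError("trial has no positive indifference point")
    return math.log(num / den)


def build_choice_set(design: TaskDesign) -> list[ChoiceTrial]:
    """Generate the non-catch trial set for a task design.

    SS amounts cover their range on an even grid; relative differences are
    log-spaced over theirs (so discount-rate indifference points spread
    evenly on the log scale); LL delays are drawn log-uniformly within
    [1 week, 6 months], constrained to exceed both the SS delay and the
    delay below which the LL option would dominate at any discount rate.
    The extreme trial pairings (min amount with min ratio, max amount with
    max ratio) are pinned so the printed LL range ($16-$170 under the
    defaults) is attained exactly.  LL screen side is counterbalanced.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_trials

    ss_amounts = np.rint(np.linspace(*design.ss_amount_range, n)).astype(int)
    ratios = np.geomspace(*design.ratio_range, n)
    rng.shuffle(ratios)
    # pin the design extremes: cheapest SS gets the minimal mark-up,
    # priciest SS the maximal one
    i_min, i_max = 0, n - 1
    j_min, j_max = int(np.argmin(ratios)), int(np.argmax(ratios))
    ratios[i_min], ratios[j_min] = ratios[j_min], ratios[i_min]
    if j_max == i_min:
        j_max = j_min
    ratios[i_max], ratios[j_max] = ratios[j_max], ratios[i_max]

    ss_delays = rng.choice(design.ss_delay_menu, size=n)
    lo_ll, hi_ll = design.ll_delay_range

    sides = np.array(["left", "right"])[np.argsort(rng.random(n)) % 2]

    trials: list[ChoiceTrial] = []
    order = rng.permutation(n)
    for tid, idx in enumerate(order):
        ss_a = int(ss_amounts[idx])
        ll_a = _ceil_dollar(ss_a * (1.0 + ratios[idx]))
        t_ss = int(ss_delays[idx])
        # informative lower bound: below this the LL option dominates for all k
        lo = max(lo_ll, t_ss + 1, int(math.floor(t_ss * ll_a / ss_a)) + 1)
        hi = max(hi_ll, lo)
        t_ll = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi + 1)))))
        t_ll = min(max(t_ll, lo), hi)
        trials.append(
            ChoiceTrial(
                trial_id=tid,
                ss_amount=float(ss_a),
                ll_amount=float(ll_a),
                ss_delay=t_ss,
                ll_delay=t_ll,
                is_catch=False,
                side_ll=str(sides[idx]),
            )
        )
    return trials


def build_catch_trials(n: int, seed: int = 0, start_id: int = 10_000) -> list[ChoiceTrial]:
    """Generate ``n`` catch trials whose sooner option strictly dominates.

    Modeled on the published example ($10 today vs. $5 in two weeks): the
    later reward is both smaller and later, so choosing it flags random or
    inattentive responding.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        # sooner option today and roughly twice as large: dominated even
        # under heavy discounting, so only lapses produce LL choices
        ss_a = int(rng.integers(10, 86))
        ll_a = max(1, int(math.floor(ss_a * rng.uniform(0.3, 0.7))))
        t_ss = 0
        t_ll = int(rng.integers(14, 181))
        trials.append(
            ChoiceTrial(
                trial_id=start_id + i,
                ss_amount=float(ss_a),
                ll_amount=float(ll_a),
                ss_delay=t_ss,
                ll_delay=t_ll,
                is_catch=True,
                side_ll="left" if i % 2 else "right",
            )
        )
    return trials


def interleave_catch_trials(
    task_trials: Sequence[ChoiceTrial],
    catch_trials: Sequence[ChoiceTrial],
    seed: int = 0,
) -> list[ChoiceTrial]:
    """Insert catch trials at seeded random positions within the task set."""
    rng = np.random.default_rng(seed)
    merged = list(task_trials)
    for ct in catch_trials:
        pos = int(rng.integers(0, len(merged) + 1))
        merged.insert(pos, ct)
    return merged


def validate_catch_responses(
    trials: Sequence[ChoiceTrial], responses: Sequence[str]
) -> tuple[bool, int]:
    """Check catch-trial responses; any choice of the dominated LL option fails.

    Returns ``(passed, n_failures)``.  A participant who fails at least one
    catch trial is excluded from discounting analysis.
    """
    if len(trials) != len(responses):
        raise ValueError("responses must align one-to-one with catch trials")
    for t in trials:
        if not t.is_catch:
            raise ValueError(f"trial {t.trial_id} is not a catch trial")
    n_fail = 0
    for resp in responses:
        if resp not in (SS, LL):
            raise ValueError(f"unknown choice code {resp!r}")
        if resp == LL:
            n_fail += 1
    return n_fail == 0, n_fail


def trials_to_frame(trials: Iterable[ChoiceTrial]) -> pd.DataFrame:
    """Serialize trials to the canonical table schema."""
    rows = [
        {
            "trial_id": t.trial_id,
            "ss_amount": t.ss_amount,
            "ss_delay_days": t.ss_delay,
            "ll_amount": t.ll_amount,
            "ll_delay_days": t.ll_delay,
            "is_catch": t.is_catch,
            "side_ll": t.side_ll,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[ChoiceTrial]:
    return [
        ChoiceTrial(
            trial_id=int(r.trial_id),
            ss_amount=float(r.ss_amount),
            ll_amount=float(r.ll_amount),
            ss_delay=int(r.ss_delay_days),
            ll_delay=int(r.ll_delay_days),
            is_catch=bool(r.is_catch),
            side_ll=str(r.side_ll),
        )
        for r in frame.itertuples(index=False)
    ]


def load_trial_table(path) -> list[ChoiceTrial]:
    """Exact-replication mode: load a deposited trial table verbatim (CSV)."""
    return frame_to_trials(pd.read_csv(path))
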
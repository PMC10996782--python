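"""Synthetic cohorts with known ground truth.

Simulated participants carry true discounting parameters, latent
future-orientation and dispositional-negativity traits, item-level
questionnaire responses consistent with target scale scores, per-trial
intertemporal choices drawn from the noisy-choice model, and
temporal-accuracy task data — so every downstream stage (scoring,
exclusions, model fitting, factor analysis, group tests, mediation) can be
exercised against a known generative truth.

Defaults mirror the study conditions the pipeline is built for: a smaller
high-risk and larger low-risk group; group means of log(k) of -4.394 and
-3.928; a standardized group effect of about 0.45 on the future-orientation
trait; a trait/log(k) correlation of about -0.26; and an EAT/negativity
correlation of about 0.31.  Latent traits come from a multivariate normal
and are mapped to bounded questionnaire targets through a Gaussian copula,
so marginal score ranges and the target correlation structure can both be
honored.  Indicator loadings on the latent traits are chosen so the
recovered factor solutions (two- and three-indicator variants) land near
the published loadings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from farsight.choice_task import LL, SS, ChoiceTrial, TaskDesign, build_catch_trials, build_choice_set
from farsight.discounting import DiscountingParams, choice_probability, hyperbolic_sv
from farsight.questionnaires import (
    EAT26_FORWARD_MAP,
    EAT26_REVERSE_MAP,
    SCALES,
    ScaleSpec,
)

# indicator loadings on the latent traits (chosen to reproduce the observed
# factor solutions: CFC/ZTPI pairwise r ~ 0.57, PFE cross-r ~ 0.15)
_FUTURE_LOADINGS = {"cfc": 0.755, "ztpi_future": 0.755, "pfe": 0.199}
_NEG_LOADINGS = {"bdi": 0.84, "stai": 0.91, "atq_na": 0.80}


@dataclass
class CohortConfig:
    """Generative conditions for a simulated cohort."""

    n_high: int = 55
    n_low: int = 97
    logk_mean_high: float = -4.394
    logk_mean_low: float = -3.928
    logk_sd: float = 1.47
    alpha_scale: float = 4.0          # half-normal scale for comparison noise
    # lapse-rate Beta shape: mode 0.02, mean 0.038 — most agents attentive,
    # yielding a realistic handful of catch-trial failures per 150 agents
    epsilon_beta: tuple[float, float] = (2.0, 50.0)
    trait_effect_d_future: float = 0.451
    trait_effect_d_negativity: float = 0.69
    r_future_logk: float = -0.26
    r_negativity_eat: float = 0.314
    r_future_negativity: float = -0.29
    n_thoughts: int = 10              # PFE listing length
    seed: int = 0

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of (logk_z, future, negativity, eat_z)."""
        r = np.eye(4)
        r[0, 1] = r[1, 0] = self.r_future_logk
        r[1, 2] = r[2, 1] = self.r_future_negativity
        r[2, 3] = r[3, 2] = self.r_negativity_eat
        return r

    def validate(self) -> None:
        if self.n_high < 0 or self.n_low < 0 or self.n_high + self.n_low == 0:
            raise ValueError("need at least one participant")
        if self.logk_sd <= 0 or self.alpha_scale <= 0:
            raise ValueError("dispersions must be positive")
        eig = np.linalg.eigvalsh(self.latent_correlation())
        if eig.min() < -1e-10:
            raise ValueError("latent correlation matrix is not positive semi-definite")


@dataclass
class AgentRecord:
    """One simulated participant with full ground truth."""

    participant_id: str
    group: str                         # "high" / "low" risk
    params: DiscountingParams
    future_orientation: float          # latent trait values
    negativity: float
    target_scores: dict
    item_responses: dict               # scale -> {item: response}
    pfe_thoughts: list
    choices: list                      # codes aligned to the task trials
    catch_responses: list
    gender: str = "female"
    income: int = 3


def simulate_agent_choices(
    params: DiscountingParams, trials: Sequence[ChoiceTrial], seed: int = 0
) -> list[str]:
    """Draw one binary choice per trial from the noisy hyperbolic model."""
    rng = np.random.default_rng(seed)
    k = math.exp(params.log_k)
    out = []
    for t in trials:
        p_ll = choice_probability(
            hyperbolic_sv(t.ss_amount, k, t.ss_delay),
            hyperbolic_sv(t.ll_amount, k, t.ll_delay),
            params.alpha,
            params.epsilon,
        )
        out.append(LL if rng.random() < p_ll else SS)
    return out


# ---------------------------------------------------------------------------
# item-level questionnaire generation


def _distribute(total: int, n_items: int, lo: int, hi: int) -> list[int]:
    """Spread an integer total over items, each within [lo, hi]."""
    if not n_items * lo <= total <= n_items * hi:
        raise ValueError(
            f"target {total} unattainable with {n_items} items in [{lo}, {hi}]"
        )
    vals = [lo] * n_items
    remaining = total - n_items * lo
    i = 0
    while remaining > 0:
        add = min(hi - vals[i], remaining)
        vals[i] += add
        remaining -= add
        i += 1
    return vals


def _eat26_items(total: int) -> dict[int, str]:
    codes = _distribute(int(total), 26, 0, 3)
    fwd = {v: k for k, v in {"Never": 0, "Often": 1, "Usually": 2, "Always": 3}.items()}
    rev = {v: k for k, v in {"Often": 0, "Sometimes": 1, "Rarely": 2, "Never": 3}.items()}
    out = {}
    for item, code in enumerate(codes, start=1):
        out[item] = rev[code] if item == 26 else fwd[code]
    return out


def _keyed_items(spec: ScaleSpec, scored_values: Sequence[int], fill: int | None = None) -> dict[int, int]:
    """Convert per-item *scored* values back to raw responses (undoing
    reverse keys); non-subscale items get a neutral filler."""
    out = {}
    used = spec.used_items
    for item, v in zip(used, scored_values):
        raw = spec.min_resp + spec.max_resp - v if item in spec.reversed_items else v
        out[item] = int(raw)
    if fill is not None:
        for item in range(1, spec.n_items + 1):
            if item not in out:
                out[item] = fill
    return out


def _sum_scale_items(spec: ScaleSpec, target: float) -> dict[int, int]:
    total = int(round(target))
    if abs(total - target) > 1e-9:
        raise ValueError(f"{spec.name} target {target} is not an attainable total")
    vals = _distribute(total, len(spec.used_items), spec.min_resp, spec.max_resp)
    return _keyed_items(spec, vals)


def _mean_scale_items(spec: ScaleSpec, target: float) -> dict[int, int]:
    n = len(spec.used_items)
    total = int(round(target * n))
    if abs(total / n - target) > 1e-9:
        raise ValueError(
            f"{spec.name} target mean {target} is not attainable with {n} items"
        )
    vals = _distribute(total, n, spec.min_resp, spec.max_resp)
    neutral = (spec.min_resp + spec.max_resp) // 2
    return _keyed_items(spec, vals, fill=neutral if spec.items else None)


def simulate_questionnaire_responses(
    target_scores: Mapping[str, float],
    seed: int = 0,
    mode: str = "deterministic",
    missing: Mapping[str, float] | None = None,
) -> dict:
    """Generate item-level responses whose scored values hit the targets.

    ``target_scores`` maps scale names (eat26, cfc, ztpi_future, pfe, bdi,
    stai, atq_na) to target scores.  In deterministic mode scoring the
    result recovers each target exactly; ``mode="noisy"`` perturbs each
    target by one scale unit at random first.  ``missing`` maps scale names
    to a fraction of items to blank, to exercise the 75%-completion rule.
    Unattainable targets raise ``ValueError``.
    """
    if mode not in ("deterministic", "noisy"):
        raise ValueError("mode must be 'deterministic' or 'noisy'")
    rng = np.random.default_rng(seed)
    missing = dict(missing or {})
    out: dict = {}
    for scale, target in target_scores.items():
        if mode == "noisy":
            if scale == "pfe":
                step = 0.1
                lo_n, hi_n = 0.0, 1.0
            elif scale == "eat26":
                step, lo_n, hi_n = 1.0, 0.0, 78.0
            else:
                spec = SCALES[scale]
                step = 1.0 if spec.scoring == "sum" else 1.0 / len(spec.used_items)
                lo_n, hi_n = spec.score_range()
            target = min(max(target + step * rng.choice((-1.0, 0.0, 1.0)), lo_n), hi_n)
        if scale == "eat26":
            total = int(round(target))
            if abs(total - target) > 1e-9 or not 0 <= total <= 78:
                raise ValueError(f"eat26 target {target} is not an attainable total")
            items: dict = _eat26_items(total)
        elif scale == "pfe":
            n = 10
            n_future = int(round(target * n))
            if abs(n_future / n - target) > 1e-9 or not 0 <= n_future <= n:
                raise ValueError(f"pfe target {target} unattainable with {n} thoughts")
            items = ["future"] * n_future + ["present"] * (n - n_future)
        else:
            spec = SCALES[scale]
            if spec.scoring == "sum":
                items = _sum_scale_items(spec, target)
            else:
                items = _mean_scale_items(spec, target)
        frac = missing.get(scale, 0.0)
        if frac > 0:
            if scale == "pfe":
                items = items[: max(0, int(round(len(items) * (1 - frac))))]
            else:
                drop = list(items)[: int(math.ceil(frac * len(items)))]
                for key in drop:
                    items[key] = None
        out[scale] = items
    return out


# ---------------------------------------------------------------------------
# cohort assembly


def _trait_targets(future: float, negativity: float, eat_z: float, group: str,
                   rng: np.random.Generator) -> dict:
    """Map latent traits to attainable questionnaire target scores."""
    lf, ln = _FUTURE_LOADINGS, _NEG_LOADINGS

    def mix(l, latent):
        return l * latent + math.sqrt(1.0 - l * l) * rng.standard_normal()

    cfc_z = mix(lf["cfc"], future)
    ztpi_z = mix(lf["ztpi_future"], future)
    pfe_z = mix(lf["pfe"], future)
    bdi_z = mix(ln["bdi"], negativity)
    stai_z = mix(ln["stai"], negativity)
    atq_z = mix(ln["atq_na"], negativity)

    u = norm.cdf(eat_z)
    if group == "high":
        eat = 21 + int(math.floor(u * 21))        # 21..41
    else:
        eat = int(math.floor(u * 21))             # 0..20

    return {
        "eat26": eat,
        "cfc": int(np.clip(round(36 + 8 * cfc_z), 12, 60)),
        "ztpi_future": float(np.clip(round((3.4 + 0.55 * ztpi_z) * 13) / 13, 1, 5)),
        "pfe": float(np.clip(round((0.40 + 0.18 * pfe_z) * 10) / 10, 0, 1)),
        "bdi": int(np.clip(round(10 + 7 * bdi_z), 0, 63)),
        "stai": int(np.clip(round(42 + 10 * stai_z), 20, 80)),
        "atq_na": float(np.clip(round((4.0 + 0.9 * atq_z) * 26) / 26, 1, 7)),
    }


@dataclass
class Cohort:
    config: CohortConfig
    design: TaskDesign
    trials: list
    catch_trials: list
    agents: list

    def manifest(self) -> dict:
        """Ground-truth record for recovery tests."""
        return {
            "seed": self.config.seed,
            "agents": [
                {
                    "participant_id": a.participant_id,
                    "group": a.group,
                    "log_k": a.params.log_k,
                    "alpha": a.params.alpha,
                    "epsilon": a.params.epsilon,
                    "future_orientation": a.future_orientation,
                    "negativity": a.negativity,
                    "target_scores": a.target_scores,
                }
                for a in self.agents
            ],
        }


def simulate_cohort(config: CohortConfig, design: TaskDesign | None = None) -> Cohort:
    """Generate a full synthetic cohort under the configured conditions.

    Per agent: latent (log_k, future orientation, negativity, EAT) values
    from the group-specific multivariate normal; questionnaire targets and
    item responses; intertemporal choices from the noisy hyperbolic model;
    catch-trial responses; gender and income covariates.  A fixed seed
    reproduces the cohort exactly.
    """
    config.validate()
    design = design or TaskDesign(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    trials = build_choice_set(design)
    catch = build_catch_trials(design.n_catch, seed=design.seed)

    corr = config.latent_correlation()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))

    agents = []
    specs = [("high", config.n_high, config.logk_mean_high, +config.trait_effect_d_future / 2,
              +config.trait_effect_d_negativity / 2),
             ("low", config.n_low, config.logk_mean_low, -config.trait_effect_d_future / 2,
              -config.trait_effect_d_negativity / 2)]
    idx = 0
    a_eps, b_eps = config.epsilon_beta
    for group, n, logk_mean, d_future, d_neg in specs:
        for _ in range(n):
            z = chol @ rng.standard_normal(4)
            log_k = logk_mean + config.logk_sd * z[0]
            future = d_future + z[1]
            negativity = d_neg + z[2]
            alpha = abs(rng.normal(0.0, config.alpha_scale)) + 0.25
            epsilon = min(float(rng.beta(a_eps, b_eps)), 0.5)
            params = DiscountingParams(log_k=log_k, alpha=alpha, epsilon=epsilon)

            targets = _trait_targets(future, negativity, z[3], group, rng)
            item_seed = int(rng.integers(0, 2**31 - 1))
            responses = simulate_questionnaire_responses(
                {k: v for k, v in targets.items() if k != "pfe"}, seed=item_seed
            )
            pfe_items = simulate_questionnaire_responses(
                {"pfe": targets["pfe"]}, seed=item_seed
            )["pfe"]

            choice_seed = int(rng.integers(0, 2**31 - 1))
            choices = simulate_agent_choices(params, trials, seed=choice_seed)
            catch_resp = simulate_agent_choices(params, catch, seed=choice_seed + 1)

            agents.append(
                AgentRecord(
                    participant_id=f"p{idx:03d}",
                    group=group,
                    params=params,
                    future_orientation=future,
                    negativity=negativity,
                    target_scores=targets,
                    item_responses=responses,
                    pfe_thoughts=list(pfe_items),
                    choices=choices,
                    catch_responses=catch_resp,
                    gender="female" if rng.random() < 0.72 else "male",
                    income=int(rng.integers(1, 8)),
                )
            )
            idx += 1
    return Cohort(config=config, design=design, trials=trials, catch_trials=catch, agents=agents)


# ---------------------------------------------------------------------------
# CSV serialization (same schemas the readers consume)


def cohort_choices_frame(cohort: Cohort) -> pd.DataFrame:
    """Long trial-response table joined to the trial attributes."""
    rows = []
    for a in cohort.agents:
        for t, resp in zip(cohort.trials, a.choices):
            rows.append(
                {
                    "participant_id": a.participant_id,
                    "trial_id": t.trial_id,
                    "ss_amount": t.ss_amount,
                    "ss_delay_days": t.ss_delay,
                    "ll_amount": t.ll_amount,
                    "ll_delay_days": t.ll_delay,
                    "is_catch": False,
                    "choice": resp,
                }
            )
    return pd.DataFrame(rows)


def cohort_item_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """One item-response table per scale (participant_id, item, response)."""
    out: dict[str, list] = {}
    for a in cohort.agents:
        for scale, items in a.item_responses.items():
            rows = out.setdefault(scale, [])
            for item, resp in items.items():
                rows.append({"participant_id": a.participant_id, "item": item, "response": resp})
        rows = out.setdefault("pfe", [])
        for i, label in enumerate(a.pfe_thoughts, start=1):
            rows.append({"participant_id": a.participant_id, "item": i, "response": label})
    return {scale: pd.DataFrame(rows) for scale, rows in out.items()}


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the canonical CSV/JSON artifacts for a simulated cohort."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from farsight.choice_task import trials_to_frame

    trials_to_frame(cohort.trials + cohort.catch_trials).to_csv(out / "trials.csv", index=False)
    cohort_choices_frame(cohort).to_csv(out / "choices.csv", index=False)
    for scale, frame in cohort_item_frames(cohort).items():
        frame.to_csv(out / f"items_{scale}.csv", index=False)
    pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "group": a.group,
                "gender": a.gender,
                "income": a.income,
            }
            for a in cohort.agents
        ]
    ).to_csv(out / "participants.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest(), fh, indent=1)
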
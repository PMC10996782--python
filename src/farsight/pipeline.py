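"""End-to-end orchestration: simulate -> score -> exclude -> fit -> factor -> test -> mediate.

The pipeline mirrors the analysis flow of the cohort design: questionnaire
items are scored and the EAT-26 cutoff assigns risk groups; two separate
exclusion streams are tracked (discounting: catch-trial failures plus
random-responding flags from the hierarchical fit; questionnaires: the 75%
completion rule plus the 3-SD factor-score outlier rule); the hyperbolic
model is fitted per risk group; future-orientation and
dispositional-negativity factor scores are extracted; and the group tests,
correlations, covariate-adjusted models and bootstrap mediation are run.
Every stage seed derives from the global seed, so a run is fully
reproducible from config + seed, and each stage writes its intermediate
artifact so any later stage can be resumed from disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from farsight.choice_task import TaskDesign, validate_catch_responses
from farsight.cohort import (
    Cohort,
    CohortConfig,
    cohort_choices_frame,
    simulate_cohort,
    write_cohort,
)
from farsight.discounting import (
    GroupPrior,
    McmcSettings,
    classify_choices,
    fit_hierarchical,
)
from farsight.factors import fit_pca_factor
from farsight.inference import (
    ancova_group_effect,
    group_ttest,
    mediate,
    pearson_correlation,
)
from farsight.questionnaires import (
    SCALES,
    apply_quality_exclusions,
    score_cfc,
    score_eat26,
    score_negativity_scales,
    score_pfe,
    score_ztpi_future,
)

DEFAULT_TAILS = {
    "logk_group": "one",
    "future_group": "one",
    "negativity_group": "two",
    "r_future_logk": "two",
    "r_eat_negativity": "two",
}


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    design: TaskDesign = field(default_factory=TaskDesign)
    # full-cohort fits carry ~3x more parameters than the small recovery
    # studies, so the pipeline default samples a little longer
    sampler: McmcSettings = field(
        default_factory=lambda: McmcSettings(n_samples=4_000, n_burnin=1_000)
    )
    prior: GroupPrior = field(default_factory=GroupPrior)
    tails: dict = field(default_factory=lambda: dict(DEFAULT_TAILS))
    n_boot: int = 10_000
    seed: int = 0
    outdir: str = "farsight_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("cohort", CohortConfig),
            ("design", TaskDesign),
            ("sampler", McmcSettings),
            ("prior", GroupPrior),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        order = ["simulate", "fit_high", "fit_low", "mediate"]
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# scoring stage


def score_item_tables(
    item_frames: dict, n_thoughts: int = 10, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score item-response tables; returns (scored, completions).

    ``item_frames`` maps scale names to long tables with columns
    ``participant_id, item, response`` (the ``pfe`` table holds thought
    labels).  ``covariates`` optionally supplies per-participant
    gender/income columns to carry along.
    """
    pids: list = []
    for frame in item_frames.values():
        for p in frame["participant_id"].unique():
            if p not in pids:
                pids.append(p)

    def _items_of(scale, pid):
        frame = item_frames[scale]
        sub = frame[frame["participant_id"] == pid]
        return {
            int(r.item): (None if pd.isna(r.response) else r.response)
            for r in sub.itertuples(index=False)
        }

    rows, comp_rows = [], []
    for pid in pids:
        eat_items = {k: v for k, v in _items_of("eat26", pid).items() if v is not None}
        eat_total, risk = score_eat26(eat_items)
        eat_nb, risk_nb = score_eat26(eat_items, exclude_bulimia=True)
        cfc_items = {k: v for k, v in _items_of("cfc", pid).items() if v is not None}
        pfe_labels = [
            v for v in item_frames["pfe"]
            .loc[item_frames["pfe"]["participant_id"] == pid]
            .sort_values("item")["response"]
            if not pd.isna(v)
        ]
        row = {
            "participant_id": pid,
            "eat26_total": eat_total,
            "eat26_total_no_bulimia": eat_nb,
            "risk_group": risk,
            "risk_group_no_bulimia": risk_nb,
            "cfc_total": score_cfc(cfc_items) if len(cfc_items) == 12 else np.nan,
            "ztpi_future_mean": score_ztpi_future(_items_of("ztpi_future", pid)),
            "pfe_ratio": score_pfe(pfe_labels),
        }
        bdi, stai, atq = score_negativity_scales(
            _items_of("bdi", pid), _items_of("stai", pid), _items_of("atq_na", pid)
        )
        row.update({"bdi_total": bdi, "stai_total": stai, "atq_na_mean": atq})
        rows.append(row)

        comp = {"participant_id": pid}
        for scale in ("eat26", "cfc", "ztpi_future", "bdi", "stai", "atq_na"):
            vals = _items_of(scale, pid)
            if scale == "eat26":
                used: tuple = tuple(range(1, 27))
            else:
                used = SCALES[scale].used_items
            present = sum(1 for i in used if vals.get(i) is not None)
            comp[scale] = present / len(used)
        comp["pfe"] = len(pfe_labels) / n_thoughts
        comp_rows.append(comp)

    scored = pd.DataFrame(rows)
    if covariates is not None:
        scored = scored.merge(covariates, on="participant_id", how="left")
    return scored, pd.DataFrame(comp_rows)


def score_cohort(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every scale for every simulated agent."""
    from farsight.cohort import cohort_item_frames

    covs = pd.DataFrame(
        [
            {"participant_id": a.participant_id, "gender": a.gender, "income": a.income}
            for a in cohort.agents
        ]
    )
    return score_item_tables(
        cohort_item_frames(cohort), n_thoughts=cohort.config.n_thoughts, covariates=covs
    )


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the analysis report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- simulate ----------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("simulate"))
    cohort = simulate_cohort(cohort_cfg, config.design)
    write_cohort(cohort, out / "cohort")
    n_eligible = len(cohort.agents)

    # --- score -------------------------------------------------------------
    scored, completions = score_cohort(cohort)
    scored.to_csv(out / "scored.csv", index=False)
    completions.to_csv(out / "completions.csv", index=False)

    if not (scored["risk_group"] == "high").any():
        raise ValueError("empty high-risk group: no EAT-26 totals above cutoff")
    if not (scored["risk_group"] == "low").any():
        raise ValueError("empty low-risk group")

    # --- questionnaire stream exclusions ------------------------------------
    retained_q, excl_completion = apply_quality_exclusions(
        scored, completions.drop(columns=["pfe"]), outlier_fields=()
    )
    future_cols = ["cfc_total", "ztpi_future_mean", "pfe_ratio"]
    fm3 = fit_pca_factor(retained_q[future_cols], n_components=1, anchor="cfc_total")
    retained_q = retained_q.assign(future_factor=fm3.scores)
    retained_q, excl_outlier = apply_quality_exclusions(
        retained_q, None, outlier_fields=("future_factor",)
    )
    q_log = pd.concat([excl_completion, excl_outlier], ignore_index=True)

    # refit factors on the final questionnaire sample
    fm_future3 = fit_pca_factor(retained_q[future_cols], anchor="cfc_total")
    fm_future2 = fit_pca_factor(
        retained_q[["cfc_total", "ztpi_future_mean"]], anchor="cfc_total"
    )
    neg_cols = ["bdi_total", "stai_total", "atq_na_mean"]
    fm_neg = fit_pca_factor(retained_q[neg_cols], anchor="bdi_total")
    retained_q = retained_q.assign(
        future_factor=fm_future3.scores,
        future_factor_2ind=fm_future2.scores,
        negativity_factor=fm_neg.scores,
    )
    retained_q.reset_index().to_csv(out / "factor_scores.csv", index=False)

    # --- discounting stream: catch trials, then hierarchical fits -----------
    catch_fail_ids = []
    for a in cohort.agents:
        passed, _ = validate_catch_responses(cohort.catch_trials, a.catch_responses)
        if not passed:
            catch_fail_ids.append(a.participant_id)
    choices = cohort_choices_frame(cohort)
    choices.to_csv(out / "choices.csv", index=False)
    choices = choices[~choices["participant_id"].isin(catch_fail_ids)]

    group_of = scored.set_index("participant_id")["risk_group"]
    fits, fit_rows = {}, []
    for group, stage in (("high", "fit_high"), ("low", "fit_low")):
        ids = [p for p in group_of.index if group_of[p] == group and p not in catch_fail_ids]
        if not ids:
            raise ValueError(f"no catch-passing participants in the {group}-risk group")
        sub = choices[choices["participant_id"].isin(ids)]
        settings = dataclasses.replace(config.sampler, seed=config.stage_seed(stage))
        fit = fit_hierarchical(sub, prior=config.prior, settings=settings)
        fits[group] = fit
        s = fit.summary.assign(group=group)
        fit_rows.append(s)
    fit_summary = pd.concat(fit_rows, ignore_index=True)
    fit_summary.to_csv(out / "fit_summary.csv", index=False)

    random_responders = fit_summary.loc[
        fit_summary["random_responder"], "participant_id"
    ].tolist()
    d_log = pd.DataFrame(
        [{"participant_id": p, "scale": "catch", "reason": "failed catch trial", "value": np.nan}
         for p in catch_fail_ids]
        + [{"participant_id": p, "scale": "discounting", "reason": "random responding",
            "value": np.nan} for p in random_responders]
    )
    pd.concat([q_log.assign(stream="questionnaire"),
               d_log.assign(stream="discounting") if len(d_log) else d_log],
              ignore_index=True).to_csv(out / "exclusions.csv", index=False)

    # --- merge analysis table ------------------------------------------------
    analyzed_d = fit_summary[~fit_summary["random_responder"]][
        ["participant_id", "logk_mean", "group"]
    ]
    merged = analyzed_d.merge(
        retained_q.reset_index()[
            ["participant_id", "future_factor", "future_factor_2ind",
             "negativity_factor", "eat26_total", "gender", "income"]
        ],
        on="participant_id",
        how="inner",
    )
    merged.to_csv(out / "analysis_table.csv", index=False)

    # --- tests ---------------------------------------------------------------
    tails = {**DEFAULT_TAILS, **config.tails}
    tests = {}
    tests["logk_group"] = group_ttest(
        merged["logk_mean"], merged["group"], tail=tails["logk_group"],
        order=("high", "low"),
    ).as_dict()
    q_groups = retained_q["risk_group"]
    tests["future_group"] = group_ttest(
        retained_q["future_factor"], q_groups, tail=tails["future_group"],
        order=("low", "high"),
    ).as_dict()
    tests["negativity_group"] = group_ttest(
        retained_q["negativity_factor"], q_groups, tail=tails["negativity_group"],
        order=("low", "high"),
    ).as_dict()
    tests["r_future_logk"] = pearson_correlation(
        merged["future_factor"], merged["logk_mean"], tail=tails["r_future_logk"]
    ).as_dict()
    tests["r_eat_negativity"] = pearson_correlation(
        retained_q["eat26_total"], retained_q["negativity_factor"],
        tail=tails["r_eat_negativity"],
    ).as_dict()

    covs = pd.DataFrame(
        {"gender": (merged["gender"] == "female").astype(float),
         "income": merged["income"].astype(float)}
    )
    tests["logk_group_ancova"] = ancova_group_effect(
        merged["logk_mean"], merged["group"], covs
    ).as_dict()

    # --- mediation -----------------------------------------------------------
    x = (merged["group"] == "high").astype(float).to_numpy()
    med = mediate(
        x,
        merged[["future_factor"]],
        merged["logk_mean"].to_numpy(),
        n_boot=config.n_boot,
        seed=config.stage_seed("mediate"),
    )
    med_parallel = mediate(
        x,
        pd.DataFrame(
            {
                "future_factor": merged["future_factor"],
                "gender": (merged["gender"] == "female").astype(float),
                "income": merged["income"].astype(float),
            }
        ),
        merged["logk_mean"].to_numpy(),
        n_boot=config.n_boot,
        seed=config.stage_seed("mediate"),
    )

    # --- report --------------------------------------------------------------
    def _group_stats(values, groups):
        df = pd.DataFrame({"v": values, "g": groups})
        return {
            g: {"mean": float(s["v"].mean()), "sd": float(s["v"].std(ddof=1)),
                "n": int(len(s))}
            for g, s in df.groupby("g")
        }

    report = {
        "seed": config.seed,
        "n_eligible": n_eligible,
        "discounting_stream": {
            "n_catch_failures": len(catch_fail_ids),
            "n_random_responders": len(random_responders),
            "n_analyzed": int(len(analyzed_d)),
            "classification_accuracy": {
                g: classify_choices(f) for g, f in fits.items()
            },
            "rhat_max": {g: f.rhat_max for g, f in fits.items()},
            "converged": {g: f.converged for g, f in fits.items()},
        },
        "questionnaire_stream": {
            "n_excluded": int(q_log["participant_id"].nunique()),
            "n_analyzed": int(len(retained_q)),
        },
        "group_logk": _group_stats(merged["logk_mean"], merged["group"]),
        "group_future": _group_stats(retained_q["future_factor"], q_groups),
        "factors": {
            "future_3ind": {
                "variance": fm_future3.first_component_variance,
                "loadings": fm_future3.loadings["PC1"].to_dict(),
            },
            "future_2ind": {
                "variance": fm_future2.first_component_variance,
                "loadings": fm_future2.loadings["PC1"].to_dict(),
            },
            "negativity": {
                "variance": fm_neg.first_component_variance,
                "loadings": fm_neg.loadings["PC1"].to_dict(),
            },
        },
        "tests": tests,
        "mediation": med.as_dict(),
        "mediation_parallel": med_parallel.as_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
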
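import json

import numpy as np
import pandas as pd
import pytest

from farsight.choice_task import LL, SS, TaskDesign
from farsight.cohort import (
    CohortConfig,
    cohort_choices_frame,
    simulate_agent_choices,
    simulate_cohort,
    simulate_questionnaire_responses,
    write_cohort,
)
from farsight.discounting import DiscountingParams, choice_probability, hyperbolic_sv
from farsight.questionnaires import (
    apply_quality_exclusions,
    score_cfc,
    score_eat26,
    score_negativity_scales,
    score_pfe,
    score_ztpi_future,
)


class TestAgentChoices:
    def test_extreme_impatience_chooses_sooner(self, trial_set, agent_params):
        # sharp value comparison (tiny alpha): the collapsed delayed option
        # is never preferred
        params = agent_params(log_k=5.0, alpha=1e-9, epsilon=0.0)
        assert set(simulate_agent_choices(params, trial_set, seed=1)) == {SS}

    def test_no_discounting_chooses_larger(self, trial_set, agent_params):
        # k -> 0: subjective value reduces to amount, and LL is larger
        params = agent_params(log_k=-50.0, alpha=1e-9, epsilon=0.0)
        assert set(simulate_agent_choices(params, trial_set, seed=1)) == {LL}

    def test_pure_noise_rate_matches_analytic_mean(self, trial_set, agent_params):
        params = agent_params(log_k=-5.3, epsilon=0.5)
        picks = []
        for seed in range(70):  # 70 x 144 > 10,000 Bernoulli draws
            picks += simulate_agent_choices(params, trial_set, seed=seed)
        frac_ll = np.mean([c == LL for c in picks])
        assert frac_ll == pytest.approx(0.5, abs=0.02)

    def test_simulation_matches_choice_model_mean(self, trial_set, agent_params):
        # average simulated LL rate ~ analytic mean of per-trial p(LL)
        params = agent_params(log_k=-4.5, alpha=5.0, epsilon=0.1)
        k = np.exp(params.log_k)
        p = np.mean(
            [
                choice_probability(
                    hyperbolic_sv(t.ss_amount, k, t.ss_delay),
                    hyperbolic_sv(t.ll_amount, k, t.ll_delay),
                    params.alpha,
                    params.epsilon,
                )
                for t in trial_set
            ]
        )
        picks = []
        for seed in range(70):
            picks += simulate_agent_choices(params, trial_set, seed=seed)
        assert np.mean([c == LL for c in picks]) == pytest.approx(p, abs=0.02)


class TestSimulateCohort:
    def test_same_seed_reproduces_exactly(self):
        cfg = CohortConfig(n_high=6, n_low=8, seed=5)
        design = TaskDesign(seed=5, n_trials=20)
        c1, c2 = simulate_cohort(cfg, design), simulate_cohort(cfg, design)
        assert json.dumps(c1.manifest()) == json.dumps(c2.manifest())
        pd.testing.assert_frame_equal(cohort_choices_frame(c1), cohort_choices_frame(c2))

    def test_group_difference_in_true_logk(self):
        cfg = CohortConfig(n_high=200, n_low=200, seed=3)
        cohort = simulate_cohort(cfg, TaskDesign(seed=3, n_trials=2))
        lk = pd.DataFrame(
            [{"g": a.group, "lk": a.params.log_k} for a in cohort.agents]
        ).groupby("g")["lk"].mean()
        configured = cfg.logk_mean_high - cfg.logk_mean_low
        assert lk["high"] - lk["low"] == pytest.approx(configured, abs=0.2)

    def test_null_trait_correlation_recovered(self):
        cfg = CohortConfig(n_high=200, n_low=200, r_future_logk=0.0, seed=4)
        cohort = simulate_cohort(cfg, TaskDesign(seed=4, n_trials=2))
        df = pd.DataFrame(
            [{"F": a.future_orientation, "lk": a.params.log_k} for a in cohort.agents]
        )
        assert abs(df.corr().iloc[0, 1]) < 0.15

    def test_invalid_correlations_rejected(self):
        cfg = CohortConfig(r_future_logk=0.9, r_future_negativity=0.9,
                           r_negativity_eat=-0.9)
        with pytest.raises(ValueError, match="positive semi-definite"):
            cfg.validate()

    def test_scoring_round_trip_recovers_targets(self):
        cfg = CohortConfig(n_high=5, n_low=5, seed=8)
        cohort = simulate_cohort(cfg, TaskDesign(seed=8, n_trials=2))
        for a in cohort.agents:
            t = a.target_scores
            total, label = score_eat26(a.item_responses["eat26"])
            assert total == t["eat26"]
            assert (label == "high") == (a.group == "high")
            assert score_cfc(a.item_responses["cfc"]) == t["cfc"]
            assert score_ztpi_future(a.item_responses["ztpi_future"]) == pytest.approx(
                t["ztpi_future"]
            )
            assert score_pfe(a.pfe_thoughts) == pytest.approx(t["pfe"])
            bdi, stai, atq = score_negativity_scales(
                a.item_responses["bdi"], a.item_responses["stai"], a.item_responses["atq_na"]
            )
            assert (bdi, stai) == (t["bdi"], t["stai"])
            assert atq == pytest.approx(t["atq_na"])

    def test_write_cohort_artifacts(self, tmp_path):
        cohort = simulate_cohort(CohortConfig(n_high=3, n_low=3, seed=1),
                                 TaskDesign(seed=1, n_trials=5))
        write_cohort(cohort, tmp_path)
        for name in ("trials.csv", "choices.csv", "participants.csv",
                     "manifest.json", "items_eat26.csv", "items_pfe.csv"):
            assert (tmp_path / name).exists()


class TestQuestionnaireGenerator:
    def test_eat26_target_hits_cutoff_boundary(self):
        items = simulate_questionnaire_responses({"eat26": 21})["eat26"]
        total, label = score_eat26(items)
        assert total == 21 and label == "high"
        items = simulate_questionnaire_responses({"eat26": 20})["eat26"]
        total, label = score_eat26(items)
        assert total == 20 and label == "low"

    def test_cfc_floor_is_all_minimum_scoring(self):
        items = simulate_questionnaire_responses({"cfc": 12})["cfc"]
        assert score_cfc(items) == 12
        # every item contributes its minimum score of 1
        for item, resp in items.items():
            assert resp == (5 if item in {3, 4, 5, 9, 10, 11, 12} else 1)

    @pytest.mark.parametrize(
        "scale,target",
        [
            ("eat26", 0), ("eat26", 45), ("eat26", 78),
            ("cfc", 37), ("cfc", 60),
            ("ztpi_future", 3.0), ("ztpi_future", 49 / 13),
            ("bdi", 30), ("stai", 57), ("atq_na", 101 / 26),
            ("pfe", 0.4), ("pfe", 1.0),
        ],
    )
    def test_deterministic_round_trip_exact(self, scale, target):
        resp = simulate_questionnaire_responses({scale: target}, seed=2)[scale]
        scorers = {
            "eat26": lambda r: score_eat26(r)[0],
            "cfc": score_cfc,
            "ztpi_future": score_ztpi_future,
            "bdi": lambda r: score_negativity_scales(r, {i: 1 for i in range(1, 21)},
                                                     {i: 1 for i in range(1, 27)})[0],
            "stai": lambda r: score_negativity_scales({i: 0 for i in range(1, 22)}, r,
                                                      {i: 1 for i in range(1, 27)})[1],
            "atq_na": lambda r: score_negativity_scales({i: 0 for i in range(1, 22)},
                                                        {i: 1 for i in range(1, 21)}, r)[2],
            "pfe": score_pfe,
        }
        assert scorers[scale](resp) == pytest.approx(target)

    def test_noisy_mode_within_one_unit(self):
        resp = simulate_questionnaire_responses({"cfc": 40}, seed=3, mode="noisy")["cfc"]
        assert abs(score_cfc(resp) - 40) <= 1

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_questionnaire_responses({"cfc": 11})
        with pytest.raises(ValueError):
            simulate_questionnaire_responses({"pfe": 0.43})

    def test_missingness_triggers_completion_rule(self):
        resp = simulate_questionnaire_responses(
            {"cfc": 40}, seed=1, missing={"cfc": 0.3}
        )["cfc"]
        completion = sum(v is not None for v in resp.values()) / 12
        scored = pd.DataFrame({"participant_id": ["p0"], "cfc_total": [np.nan]})
        comp = pd.DataFrame({"participant_id": ["p0"], "cfc": [completion]})
        retained, log = apply_quality_exclusions(scored, comp, outlier_fields=())
        assert len(retained) == 0
        assert log.iloc[0]["reason"] == "insufficient responses"
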
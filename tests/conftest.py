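import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from farsight.choice_task import TaskDesign, build_choice_set
from farsight.cohort import simulate_agent_choices
from farsight.discounting import DiscountingParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design() -> TaskDesign:
    return TaskDesign(seed=0)


@pytest.fixture(scope="session")
def trial_set(default_design):
    return build_choice_set(default_design)


def choices_frame(trials, agents):
    """Long choice table for (participant_id, DiscountingParams, seed) specs."""
    rows = []
    for pid, params, seed in agents:
        ch = simulate_agent_choices(params, trials, seed=seed)
        for t, c in zip(trials, ch):
            rows.append(
                dict(
                    participant_id=pid,
                    ss_amount=t.ss_amount,
                    ss_delay_days=t.ss_delay,
                    ll_amount=t.ll_amount,
                    ll_delay_days=t.ll_delay,
                    choice=c,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def agent_params():
    def make(log_k, alpha=2.0, epsilon=0.02):
        return DiscountingParams(log_k=log_k, alpha=alpha, epsilon=epsilon)

    return make
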
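# farsight

Analysis pipeline for studies linking **eating-disorder risk** to
**intertemporal choice** and **future-oriented cognition**: hierarchical
Bayesian estimation of delay-discounting rates from binary choices,
deterministic questionnaire scoring with preregistration-style exclusion
rules, latent factor scores via PCA with varimax rotation, subjective
time-perception metrics, and percentile-bootstrap mediation — plus a
synthetic-cohort generator with known ground truth, so the entire analysis
can be validated end to end without human data.

It is written for behavioral/clinical researchers who run online
intertemporal-choice batteries (smaller-sooner vs. larger-later monetary
trade-offs) alongside questionnaires such as the EAT-26, CFC, ZTPI, BDI and
STAI, and want a tested, reproducible route from raw item- and trial-level
CSVs to group statistics and mediation models.

## The model

Each choice pits a smaller-sooner reward (amount $A_{SS}$, delay
$t_{SS}$ days) against a larger-later one ($A_{LL}$, $t_{LL}$). Subjective
value follows hyperbolic discounting,

$$SV(A, t) = \frac{A}{1 + k\,t},$$

with discount rate $k$ (reported as $\log k$; lower = more farsighted). The
probability of choosing the larger-later option is a lapse-compressed
cumulative-normal function of the value difference,

$$P(LL) = \varepsilon + (1 - 2\varepsilon)\,\Phi\!\left(\frac{SV_{LL} - SV_{SS}}{\alpha}\right),$$

where $\alpha$ is the comparison-acuity noise scale (money units) and
$\varepsilon \in [0, 0.5]$ the lapse (random-responding) rate. Participant
log-discount-rates are partially pooled through a group level,
$\log k_i \sim \mathcal N(\mu, \sigma)$ with $\mu \sim \mathcal N(-5.3,
2.5)$ — a prior centred where the default 144-trial choice set predicts an
even smaller-sooner/larger-later split. Sampling is Metropolis-within-Gibbs
(4 chains; convergence checked with split-chain rank-normalized
$\hat R \le 1.01$). The constant-sensitivity (Ebert–Prelec) discount
function $SV = A\,e^{-(a t)^b}$ is also provided.

Downstream, future orientation is the first principal component (varimax
rotation, unit-variance scores) of the standardized CFC total, ZTPI future
subscale mean and PFE future-thought ratio; dispositional negativity is
built identically from BDI, STAI and ATQ-NA. Group contrasts use
pooled-variance t-tests (directional hypotheses one-tailed), and the
mediation of the group difference in $\log k$ by future orientation is
tested with OLS path models and a percentile bootstrap of the partial
standardized indirect effect $a \cdot b$ (outcome z-scored, binary group on
its 0/1 scale).

## Worked example

Fit two simulated participants — one impulsive, one patient — on the
default 144-trial choice set:

```python
import pandas as pd
from farsight import (TaskDesign, build_choice_set, McmcSettings,
                      fit_hierarchical, classify_choices)
from farsight.cohort import simulate_agent_choices
from farsight.discounting import DiscountingParams

trials = build_choice_set(TaskDesign(seed=0))
agents = [("impulsive", DiscountingParams(log_k=-3.5, alpha=2.0, epsilon=0.02), 1),
          ("patient",   DiscountingParams(log_k=-6.0, alpha=2.0, epsilon=0.02), 2)]
rows = []
for pid, params, seed in agents:
    for t, c in zip(trials, simulate_agent_choices(params, trials, seed=seed)):
        rows.append(dict(participant_id=pid, ss_amount=t.ss_amount,
                         ss_delay_days=t.ss_delay, ll_amount=t.ll_amount,
                         ll_delay_days=t.ll_delay, choice=c))
fit = fit_hierarchical(pd.DataFrame(rows), settings=McmcSettings(seed=0))
print(fit.summary[["participant_id", "logk_mean", "logk_sd",
                   "epsilon_mean", "rhat_max"]].round(3))
print("accuracy:", round(classify_choices(fit), 3))
```

```
  participant_id  logk_mean  logk_sd  epsilon_mean  rhat_max
0      impulsive     -3.564    0.105         0.023     1.004
1        patient     -6.073    0.083         0.015     1.002
accuracy: 0.903
```

The posterior means recover the generating log-discount-rates (−3.5, −6.0)
within a tenth of a log unit, all chains converge, and the fitted model
classifies 90% of the simulated choices correctly.

The full pipeline (simulate → score → exclude → fit → factors → tests →
mediation) runs from the command line:

```bash
farsight pipeline --seed 7 --out myrun
```

writing per-stage CSV artifacts, an exclusion ledger and a JSON report with
group descriptives, test results and the mediation decomposition. Single
stages (`simulate`, `score`, `fit`, `factors`, `analyze`) can be resumed
from a run directory.

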
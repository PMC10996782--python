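# Methods

## Choice task construction

A trial offers a smaller-sooner (SS) and a larger-later (LL) hypothetical
monetary reward. The default design has 144 trials: SS amounts cover
$15–$85 on an even grid; the relative LL mark-up (LL/SS − 1) is log-spaced
over 2%–100% so indifference discount rates spread evenly on the log scale;
SS delays are drawn from {today, 2 weeks, 1 month} = {0, 14, 30} days and
LL delays log-uniformly within 1 week–6 months = [7, 180] days. Calendar
conversions (1 week = 7 d, 1 month = 30 d, 6 months = 180 d, 1 year =
365 d) are fixed conventions. LL amounts are rounded *up* to whole dollars:
this reproduces both printed endpoints of the LL range ($15 × 1.02 → $16
and $85 × 2.00 → $170) and guarantees LL > SS after rounding.

Two constraints shape the delay sampler. First, every trial must be
*informative*: a finite k* > 0 must exist at which the two options'
hyperbolic values are equal, which requires
t_LL > t_SS · (A_LL / A_SS); the LL delay's lower bound enforces this.
Second, the set should *balance* near log k = −5.3 — a noiseless hyperbolic
chooser with that discount rate should split roughly evenly between SS and
LL — because the group-level prior is centred there. With log-spaced
mark-ups (geometric mean ≈ 0.14) and log-uniform LL delays (geometric mean
≈ 35 d), the median indifference point lands at ≈ −5.4, within a few tenths
of the prior mean across seeds. The extreme amount/ratio pairings are
pinned so the $16/$170 range is attained exactly in every generated set;
LL screen side is counterbalanced 72/72.

Catch trials invert the trade-off (later **and** smaller, e.g. $50 today
vs. $25 in 2 months). The sooner option is anchored at today so that its
subjective value is undiscounted: with both options delayed, heavy
discounters can fail a "dominated" trial through comparison noise alone,
which would confound the attention screen. Any LL choice on a catch trial
excludes the participant from discounting analysis (the strictest reading
of failing a catch trial). A deposited trial table can replace the
generator verbatim (`load_trial_table`) for exact replication.

## Hierarchical discounting model

Observation model per participant i and trial t:

    SV(A, t) = A / (1 + k_i t),      k_i = exp(log_k_i)
    P(LL)    = eps_i + (1 − 2 eps_i) Φ((SV_LL − SV_SS) / alpha_i)

Priors (made explicit here because the source toolbox's defaults are not
printed; all configurable via `GroupPrior`):

| parameter | prior | default | rationale |
|---|---|---|---|
| group mean mu | Normal(−5.3, 2.5) | fixed | choice-set balance point; SD is the toolbox default |
| group SD sigma | HalfNormal(2.5) | fixed | weakly informative on the log scale |
| log_k_i | Normal(mu, sigma) | — | partial pooling |
| alpha_i | HalfNormal(10) | money units | SV differences span roughly $0–$85 |
| eps_i | Beta(1.1, 10.9) on [0, 0.5] | — | mode near 0.01, mass below 0.3 |

Risk groups are fitted separately so their posteriors stay independent.
Sampling is Metropolis-within-Gibbs: vectorized random-walk updates per
participant for log_k (natural scale), alpha (log scale) and eps (logit of
eps/0.5), an exact conjugate normal draw for mu, and a log-scale random
walk for sigma. Step sizes adapt toward 44% acceptance during warm-up only
(Robbins–Monro), preserving detailed balance afterwards; two sweeps of the
participant-level blocks are made per stored draw to roughly halve
autocorrelation time. Chains initialize from a coarse per-participant grid
MLE of log_k with overdispersed jitter. Convergence uses split-chain
rank-normalized R-hat (arviz) with the 1.01 threshold; a violating fit is
flagged and warned about, never silently accepted.

Sampler sizes: the default (4 chains × 2,500 samples, 500 burn-in; 8,000
retained draws) is the package's working scale, chosen so a 40-participant
fit takes well under a minute on one CPU while recovering a log_k grid of
{−7, −5.3, −4, −2.5} with correlation > 0.99, per-value bias below 0.1 and
all R-hat ≤ 1.01; `McmcSettings.paper_scale()` constructs the full-scale
4 × 25,000/1,000 (96,000 retained draws) configuration. The full-cohort
pipeline default samples a little longer (4 × 4,000/1,000) because it
carries ~3× more parameters per fit.

Point estimates for downstream statistics are posterior means of log_k.
Classification accuracy predicts LL iff fitted P(LL) > 0.5 at
posterior-mean parameters; an exact tie predicts SS. Random responding is
flagged when the posterior median of eps ≥ 0.25 **or** the participant's
in-sample predictive accuracy ≤ 0.55 (the source toolbox's exact warning
rule is not published; both thresholds are arguments). The accuracy arm is
what catches pure coin-flippers robustly, because the likelihood for such
data is degenerate between "eps ≈ 0.5" and "alpha very large" and the
posterior can put mass on either explanation.

## Questionnaire scoring

Published keys throughout. EAT-26: items 1–25 coded
Never/Rarely/Sometimes → 0, Often → 1, Usually → 2, Always → 3; item 26
reverse-coded; the six-label frequency menu is accepted (with the three
low-frequency labels sharing code 0) and the label map is configurable
because instruments in the field vary between 5- and 6-label displays.
Risk is "high" iff total > 20 (i.e., ≥ 21). The anorexia-specific variant
drops the binge/purge items 4, 9, 25 before summing and reapplies the same
cutoff. CFC: 12 items on 1–5 with items 3–5, 9–12 reversed (total 12–60).
ZTPI future subscale: mean of items {6, 9, 10, 13, 18, 21, 24, 30, 40, 43,
45, 51, 56} with 9, 24, 56 reversed (the published key; the source study
names the subscale but not the items). PFE: fraction of up to 10 listed
thoughts labeled "future". BDI: sum (0–63). STAI trait: sum with the nine
anxiety-absent items reversed (20–80). ATQ-NA: item mean on 1–7; the
short-form's reverse key varies by version, so the default spec applies
none and a replacement `ScaleSpec` can supply one.

Exclusions (questionnaire stream): completion < 75% on any used scale, or
a configured score (by default the future-orientation factor score) more
than 3 SD from the sample mean. The outlier rule is single-pass — mean and
SD come from the full pre-exclusion sample — because no iteration rule is
published and iterative trimming changes the estimand.

## Latent factors

Indicators are standardized before the SVD (correlation-matrix PCA): the
indicators live on incommensurate scales (a 12–60 sum vs. a 0–1 ratio), so
covariance PCA would be dominated by the widest one. Loadings are reported
as indicator–component correlations; a component's variance proportion is
its rotated variance divided by the number of indicators. Varimax rotation
(standard Kaiser iteration) applies when more than one component is
retained; on a single retained component it is the identity, and the
single-component solution is reported as such. Scores are projections onto
the first component, scaled to unit sample variance and oriented so the
anchor indicator (CFC for future orientation, BDI for negativity) loads
positively. Both the 3-indicator (CFC, ZTPI-future, PFE) and 2-indicator
(CFC, ZTPI-future) future-orientation variants are first-class.

## Temporal accuracy

Interval production: signed error (produced − target), averaged within the
1 Hz block (targets 20/30/40/50 s) and the 0.5 Hz block (15/20/25/30 s)
separately; the "estimate" is operationalized as elapsed time at the
participant's stop response. Horizon estimation: with the 1-week trial as
anchor, each later horizon yields objective growth (T − 7)/7 and subjective
growth (S − S_anchor)/S_anchor from the slider; the participant summary is
the arithmetic mean of per-trial subjective/objective ratios (the aggregate
is unnamed in the field; the mean is the simplest unbiased choice). The
ratio cancels the slider's unknown numeric range except when the anchor
response is exactly 0, which is flagged as undefined.

## Inference

Group contrasts are pooled-variance t-tests (df = n1 + n2 − 2, matching the
reported df convention; Welch is deliberately not used), one-tailed for the
directional discounting and future-orientation hypotheses and two-tailed
otherwise; the tail map is configuration. Effect size is pooled-SD Cohen's
d. Covariate control is a type-II ANCOVA F test for the group term.

Mediation uses OLS path models: a from M ~ X (+ covariates), b and c′ from
Y ~ X + M (+ covariates), c from Y ~ X (+ covariates), so the decomposition
c = c′ + Σ a_j b_j holds exactly. The partial standardized indirect effect
z-scores Y and keeps the binary group on its 0/1 scale; within each of the
(default 10,000) case-resampling bootstrap replicates Y is re-standardized
on that replicate. Intervals are percentile (the published macro's interval
type is not stated; the choice is an argument). Parallel mediators share a
single outcome model and report one indirect effect each.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: a
high-risk group (n = 55) and low-risk group (n = 97); true log_k means of
−4.394 (high) and −3.928 (low) with SD 1.47; a latent future-orientation
trait with a standardized group effect of 0.451 and a −0.26 correlation
with log_k; dispositional negativity with a 0.69 group effect, −0.29
correlation with future orientation and 0.314 with the EAT score. Latents
are multivariate normal and map to bounded integer questionnaire targets
through a Gaussian copula, so score ranges and the correlation structure
are both honored; item-level responses are then constructed to score to
those targets exactly (deterministic mode), which makes the
generator/scorer round trip an exact test. Indicator loadings on the
latent traits (0.755/0.755/0.199 for CFC/ZTPI/PFE; 0.84/0.91/0.80 for
BDI/STAI/ATQ-NA) were chosen so the recovered factor solutions land near
the field-typical ones (3-indicator first component ≈ 55% of variance with
a weak PFE loading; 2-indicator ≈ 79%).

Subject-level nuisance parameters, for which no generative values are
published: alpha ~ |Normal(0, 4)| + 0.25 (money units) and
eps ~ Beta(2, 50) (mode 0.02, mean 0.038), chosen so that classification
accuracy of the fitted model lands in the high-80s% and a realistic
handful of agents per ~150 fail catch trials or trip the random-responding
screen.

What the generator does **not** emulate: response times, learning or order
effects, item-level psychometric structure beyond the target scores
(items within a scale are filled deterministically, not sampled from an
IRT model), and temporal-accuracy task data. Passing tests therefore
demonstrate that the pipeline recovers known generative structure — not
that any particular human dataset will show these effects. Observed
statistics on scored quantities are slightly attenuated relative to the
configured latent values (the factor score correlates ≈ 0.85 with its
latent), which is the expected behavior of measurement, not a calibration
error.

## Numerical choices and degenerate inputs

Choice probabilities are clipped to [1e-12, 1 − 1e-12] inside the
likelihood. Zero-trial participants are allowed in a fit (their posterior
reflects the hierarchy alone); a fit with zero participants is an error.
Constant indicators, constant mediators, rank-deficient designs and
zero-variance correlations raise immediately with the offending column
named. Bootstrap and MCMC results are bit-reproducible under a fixed seed;
every pipeline stage seed derives deterministically from the global seed.

## Known limitations

- The sampler is random-walk Metropolis: adequate at these problem sizes,
  but gradient-based samplers would scale better to many more trials or
  hierarchical alpha/eps.
- The random-responder rule is a reconstruction; studies using the original
  toolbox should verify flag agreement on their own data before pooling.
- The EAT-26 group assignment treats totals of exactly 20 as low risk
  (strict "> 20"); instruments or sites using "≥ 20" must adjust the
  cutoff argument.
- Mediation is a statistical decomposition, not a causal identification;
  nothing here licenses causal claims beyond the design's own logic.
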
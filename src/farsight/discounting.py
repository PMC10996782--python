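"""Hierarchical Bayesian estimation of delay-discounting parameters.

The observation model for participant *i* on trial *t* is

    SV(A, t) = A / (1 + k_i t)                     (hyperbolic discounting)
    p(choose LL) = eps_i + (1 - 2 eps_i) * Phi((SV_LL - SV_SS) / alpha_i)

where ``k_i = exp(log_k_i)`` is the discount rate (1/day), ``alpha_i`` the
comparison-acuity noise scale (money units) and ``eps_i`` in [0, 0.5] the
lapse (random-responding) rate.  ``Phi`` is the standard normal CDF.

Participant-level log discount rates are partially pooled through a group
level: ``log_k_i ~ N(mu, sigma)`` with ``mu ~ N(-5.3, 2.5)`` (a prior
centred where the task's choice set predicts an even SS/LL split) and
``sigma ~ HalfNormal(2.5)``.  alpha and eps get independent weakly
informative priors (HalfNormal and truncated Beta respectively).

Sampling is Metropolis-within-Gibbs: random-walk proposals for the
participant-level parameters (vectorized across participants, step sizes
adapted during warm-up only), an exact conjugate Gibbs draw for ``mu`` and
a log-scale random walk for ``sigma``.  Convergence is assessed with the
split-chain rank-normalized R-hat (via arviz); a fit with any R-hat above
1.01 is flagged as non-converged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

SS = "SS"
LL = "LL"

_RHAT_THRESHOLD = 1.01


# ---------------------------------------------------------------------------
# discount and choice functions


def hyperbolic_sv(amount, k, t):
    """Hyperbolic subjective value ``A / (1 + k t)``.

    ``amount`` in money units, ``k`` the discount rate per day, ``t`` the
    delay in days.  Equals ``amount`` at t=0 and decreases in both k and t.
    """
    amount = np.asarray(amount, dtype=float)
    k = np.asarray(k, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(k < 0) or np.any(t < 0) or np.any(amount < 0):
        raise ValueError("amount, k and t must be non-negative")
    out = amount / (1.0 + k * t)
    return out if out.ndim else float(out)


def ebert_prelec_sv(amount, a, b, t):
    """Constant-sensitivity subjective value ``A * exp(-(a t)^b)``.

    ``a`` is impatience, ``b`` time sensitivity; ``b = 1`` recovers
    exponential discounting and ``a = 0`` means no discounting.
    """
    amount = np.asarray(amount, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(a < 0) or np.any(t < 0):
        raise ValueError("a and t must be non-negative")
    if np.any(b <= 0):
        raise ValueError("b must be positive")
    out = amount * np.exp(-np.power(a * t, b))
    return out if out.ndim else float(out)


def choice_probability(sv_ss, sv_ll, alpha, epsilon):
    """Probability of choosing the larger-later option.

    ``eps + (1 - 2 eps) * Phi((SV_LL - SV_SS) / alpha)``: a cumulative-normal
    psychometric function of the subjective-value difference, compressed
    into [eps, 1 - eps] by the lapse rate.
    """
    sv_ss = np.asarray(sv_ss, dtype=float)
    sv_ll = np.asarray(sv_ll, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if np.any((epsilon < 0) | (epsilon > 0.5)):
        raise ValueError("epsilon must lie in [0, 0.5]")
    out = epsilon + (1.0 - 2.0 * epsilon) * ndtr((sv_ll - sv_ss) / alpha)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class DiscountingParams:
    """Per-participant generative/estimated parameters."""

    log_k: float
    alpha: float
    epsilon: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_k):
            raise ValueError("log_k must be finite")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 0.5]")


@dataclass
class GroupPrior:
    """Priors for one risk group (groups are fitted separately)."""

    logk_mean: float = -5.3
    logk_sd: float = 2.5
    logk_group_sd_scale: float = 2.5   # HalfNormal scale for sigma
    alpha_scale: float = 10.0          # HalfNormal scale, money units
    epsilon_a: float = 1.1             # Beta shape, truncated to [0, 0.5]
    epsilon_b: float = 10.9

    def validate(self) -> None:
        if self.logk_sd <= 0 or self.logk_group_sd_scale <= 0 or self.alpha_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.epsilon_a <= 0 or self.epsilon_b <= 0:
            raise ValueError("Beta shapes must be positive")


@dataclass
class McmcSettings:
    """Sampler settings.  ``n_samples`` counts all draws per chain including
    the ``n_burnin`` discarded as warm-up (retained = n_samples - n_burnin).
    """

    n_chains: int = 4
    n_samples: int = 2_500
    n_burnin: int = 500
    seed: int = 0

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcSettings":
        """Full-scale settings: 4 chains x 25,000 samples, 1,000 burn-in
        (96,000 retained draws)."""
        return cls(n_chains=4, n_samples=25_000, n_burnin=1_000, seed=seed)

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_samples - self.n_burnin)

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for R-hat")
        if not 0 <= self.n_burnin < self.n_samples:
            raise ValueError("require 0 <= n_burnin < n_samples")


@dataclass
class GroupFit:
    """Posterior summary for one fitted group."""

    participant_ids: list
    summary: pd.DataFrame
    posterior: dict            # name -> array (chain, draw[, participant])
    rhat: pd.DataFrame
    converged: bool
    settings: McmcSettings
    prior: GroupPrior
    _data: dict = field(repr=False, default_factory=dict)

    @property
    def rhat_max(self) -> float:
        return float(np.nanmax(self.rhat.to_numpy()))


# ---------------------------------------------------------------------------
# data preparation


_REQUIRED_COLS = ["participant_id", "ss_amount", "ss_delay_days", "ll_amount", "ll_delay_days", "choice"]


def _prepare_arrays(choices: pd.DataFrame, participants: Sequence | None):
    """Pack per-participant trials into padded (P, T) arrays with a mask."""
    missing = [c for c in _REQUIRED_COLS if c not in choices.columns]
    if missing:
        raise ValueError(f"choices table missing columns: {missing}")
    if "is_catch" in choices.columns:
        choices = choices.loc[~choices["is_catch"].astype(bool)]
    bad = set(choices["choice"]) - {SS, LL}
    if bad:
        raise ValueError(f"unknown choice codes: {sorted(bad)}")

    if participants is None:
        participants = list(pd.unique(choices["participant_id"]))
    else:
        participants = list(participants)
    if len(participants) == 0:
        raise ValueError("empty group: no participants to fit")

    groups = {pid: df for pid, df in choices.groupby("participant_id")}
    t_max = max((len(groups[p]) for p in participants if p in groups), default=0)
    t_max = max(t_max, 1)
    P = len(participants)
    A_ss = np.zeros((P, t_max))
    A_ll = np.zeros((P, t_max))
    D_ss = np.zeros((P, t_max))
    D_ll = np.ones((P, t_max))
    y = np.zeros((P, t_max))
    mask = np.zeros((P, t_max))
    for i, pid in enumerate(participants):
        df = groups.get(pid)
        if df is None or len(df) == 0:
            continue
        n = len(df)
        A_ss[i, :n] = df["ss_amount"].to_numpy(float)
        A_ll[i, :n] = df["ll_amount"].to_numpy(float)
        D_ss[i, :n] = df["ss_delay_days"].to_numpy(float)
        D_ll[i, :n] = df["ll_delay_days"].to_numpy(float)
        y[i, :n] = (df["choice"].to_numpy() == LL).astype(float)
        mask[i, :n] = 1.0
    return participants, dict(A_ss=A_ss, A_ll=A_ll, D_ss=D_ss, D_ll=D_ll, y=y, mask=mask)


def _loglik(data, log_k, alpha, eps):
    """Per-participant Bernoulli log likelihood, vectorized over participants."""
    k = np.exp(log_k)[:, None]
    dsv = data["A_ll"] / (1.0 + k * data["D_ll"]) - data["A_ss"] / (1.0 + k * data["D_ss"])
    p = eps[:, None] + (1.0 - 2.0 * eps[:, None]) * ndtr(dsv / alpha[:, None])
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = data["y"] * np.log(p) + (1.0 - data["y"]) * np.log1p(-p)
    return (ll * data["mask"]).sum(axis=1)


def _grid_mle_logk(data, grid=None):
    """Crude per-participant grid MLE of log_k used only to initialize chains."""
    if grid is None:
        grid = np.linspace(-9.0, -1.0, 33)
    P = data["y"].shape[0]
    best = np.full(P, -5.3)
    best_ll = np.full(P, -np.inf)
    alpha = np.full(P, 3.0)
    eps = np.full(P, 0.02)
    for g in grid:
        ll = _loglik(data, np.full(P, g), alpha, eps)
        upd = ll > best_ll
        best[upd] = g
        best_ll[upd] = ll[upd]
    has_data = data["mask"].sum(axis=1) > 0
    best[~has_data] = -5.3
    return best


# ---------------------------------------------------------------------------
# the sampler


def _run_chain(data, prior: GroupPrior, n_samples: int, n_burnin: int, rng, init_logk):
    P = data["y"].shape[0]
    n_keep = n_samples - n_burnin

    log_k = init_logk + rng.normal(0.0, 0.5, P)
    alpha = np.abs(rng.normal(3.0, 1.0, P)) + 0.5
    eps = rng.uniform(0.01, 0.10, P)
    mu = float(np.mean(log_k))
    sigma = float(np.std(log_k) + 0.5)

    ll_cur = _loglik(data, log_k, alpha, eps)

    step_k = np.full(P, 0.3)
    step_a = np.full(P, 0.3)
    step_e = np.full(P, 0.5)
    step_s = 0.3

    out = {
        "log_k": np.empty((n_keep, P)),
        "alpha": np.empty((n_keep, P)),
        "epsilon": np.empty((n_keep, P)),
        "mu_logk": np.empty(n_keep),
        "sigma_logk": np.empty(n_keep),
    }

    def _adapt(step, accepted, it):
        # Robbins-Monro toward ~0.44 acceptance (scalar-at-a-time optimum)
        gamma = (it + 1.0) ** -0.6
        return step * np.exp(gamma * (accepted - 0.44))

    for it in range(n_samples):
        adapting = it < n_burnin

        # two sweeps over the participant-level blocks per stored draw
        # (random-walk chains are cheap here; the extra sweep roughly
        # halves the autocorrelation time)
        for _sweep in range(2):
            # --- log_k block (random walk, per participant)
            prop = log_k + step_k * rng.standard_normal(P)
            ll_prop = _loglik(data, prop, alpha, eps)
            lp = ll_prop - ll_cur
            lp += (-0.5 * ((prop - mu) ** 2 - (log_k - mu) ** 2) / sigma**2)
            acc = np.log(rng.random(P)) < lp
            log_k = np.where(acc, prop, log_k)
            ll_cur = np.where(acc, ll_prop, ll_cur)
            if adapting:
                step_k = _adapt(step_k, acc.astype(float), it)

            # --- alpha block (log-scale random walk, HalfNormal prior)
            prop_a = alpha * np.exp(step_a * rng.standard_normal(P))
            ll_prop = _loglik(data, log_k, prop_a, eps)
            lp = ll_prop - ll_cur
            lp += -0.5 * (prop_a**2 - alpha**2) / prior.alpha_scale**2
            lp += np.log(prop_a) - np.log(alpha)  # Jacobian of the log transform
            acc = np.log(rng.random(P)) < lp
            alpha = np.where(acc, prop_a, alpha)
            ll_cur = np.where(acc, ll_prop, ll_cur)
            if adapting:
                step_a = _adapt(step_a, acc.astype(float), it)

            # --- epsilon block (logit of eps/0.5, truncated Beta prior)
            u = logit(eps / 0.5)
            u_prop = u + step_e * rng.standard_normal(P)
            prop_e = 0.5 * expit(u_prop)
            ll_prop = _loglik(data, log_k, alpha, prop_e)
            lp = ll_prop - ll_cur
            lp += (prior.epsilon_a - 1.0) * (np.log(prop_e) - np.log(eps))
            lp += (prior.epsilon_b - 1.0) * (np.log1p(-prop_e) - np.log1p(-eps))
            # Jacobian d eps / d u = eps (1 - 2 eps)
            lp += np.log(prop_e) + np.log1p(-2.0 * prop_e) - np.log(eps) - np.log1p(-2.0 * eps)
            acc = np.log(rng.random(P)) < lp
            eps = np.where(acc, prop_e, eps)
            ll_cur = np.where(acc, ll_prop, ll_cur)
            if adapting:
                step_e = _adapt(step_e, acc.astype(float), it)

        # --- mu: exact conjugate normal draw
        prec = P / sigma**2 + 1.0 / prior.logk_sd**2
        mean = (log_k.sum() / sigma**2 + prior.logk_mean / prior.logk_sd**2) / prec
        mu = float(rng.normal(mean, math.sqrt(1.0 / prec)))

        # --- sigma: log-scale random walk, HalfNormal prior
        s_prop = sigma * math.exp(step_s * rng.standard_normal())
        lp = -P * (math.log(s_prop) - math.log(sigma))
        lp += -0.5 * np.sum((log_k - mu) ** 2) * (1.0 / s_prop**2 - 1.0 / sigma**2)
        lp += -0.5 * (s_prop**2 - sigma**2) / prior.logk_group_sd_scale**2
        lp += math.log(s_prop) - math.log(sigma)
        if math.log(rng.random()) < lp:
            sigma = s_prop
            if adapting:
                step_s = float(_adapt(np.array(step_s), 1.0, it))
        elif adapting:
            step_s = float(_adapt(np.array(step_s), 0.0, it))

        if it >= n_burnin:
            j = it - n_burnin
            out["log_k"][j] = log_k
            out["alpha"][j] = alpha
            out["epsilon"][j] = eps
            out["mu_logk"][j] = mu
            out["sigma_logk"][j] = sigma

    return out


def _compute_rhat(posterior: dict, participant_ids) -> pd.DataFrame:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(
            {k: v if v.ndim == 3 else v[:, :, None] for k, v in posterior.items()}
        )
        rh = az.rhat(ds)
    rows = {}
    for name in ("log_k", "alpha", "epsilon"):
        rows[name] = np.atleast_1d(rh[name].to_numpy())
    per_part = pd.DataFrame(rows, index=participant_ids)
    # group-level parameters are broadcast as extra rows
    extra = pd.DataFrame(
        {
            "log_k": [float(np.atleast_1d(rh["mu_logk"].to_numpy())[0]),
                      float(np.atleast_1d(rh["sigma_logk"].to_numpy())[0])],
            "alpha": [np.nan, np.nan],
            "epsilon": [np.nan, np.nan],
        },
        index=["__mu__", "__sigma__"],
    )
    out = pd.concat([per_part, extra])
    return out


def fit_hierarchical(
    choices: pd.DataFrame,
    prior: GroupPrior | None = None,
    settings: McmcSettings | None = None,
    participants: Sequence | None = None,
) -> GroupFit:
    """Fit the hierarchical hyperbolic model to one group's choice data.

    ``choices`` holds one row per (participant, trial) with columns
    ``participant_id, ss_amount, ss_delay_days, ll_amount, ll_delay_days,
    choice`` (codes "SS"/"LL"); rows flagged ``is_catch`` are excluded from
    the likelihood.  Groups (e.g. high vs. low risk) should be fitted
    separately to keep their posteriors independent.

    ``participants`` optionally fixes the participant list; listed ids with
    no trials contribute no likelihood and their posterior reflects the
    hierarchy alone.
    """
    prior = prior or GroupPrior()
    settings = settings or McmcSettings()
    prior.validate()
    settings.validate()

    pids, data = _prepare_arrays(choices, participants)
    init_logk = _grid_mle_logk(data)

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = [
        _run_chain(data, prior, settings.n_samples, settings.n_burnin,
                   np.random.default_rng(s), init_logk)
        for s in seeds
    ]
    posterior = {k: np.stack([c[k] for c in chains]) for k in chains[0]}

    rhat = _compute_rhat(posterior, pids)
    converged = bool(np.nanmax(rhat.to_numpy()) <= _RHAT_THRESHOLD)
    if not converged:
        warnings.warn(
            f"MCMC did not converge: max R-hat = {np.nanmax(rhat.to_numpy()):.4f} > {_RHAT_THRESHOLD}",
            RuntimeWarning,
        )

    lk = posterior["log_k"].reshape(-1, len(pids))
    al = posterior["alpha"].reshape(-1, len(pids))
    ep = posterior["epsilon"].reshape(-1, len(pids))
    summary = pd.DataFrame(
        {
            "participant_id": pids,
            "logk_mean": lk.mean(axis=0),
            "logk_median": np.median(lk, axis=0),
            "logk_sd": lk.std(axis=0, ddof=1),
            "logk_hdi_2.5": np.percentile(lk, 2.5, axis=0),
            "logk_hdi_97.5": np.percentile(lk, 97.5, axis=0),
            "alpha_mean": al.mean(axis=0),
            "epsilon_mean": ep.mean(axis=0),
            "epsilon_median": np.median(ep, axis=0),
            "rhat_max": rhat.loc[pids].max(axis=1).to_numpy(),
        }
    )

    fit = GroupFit(
        participant_ids=pids,
        summary=summary,
        posterior=posterior,
        rhat=rhat,
        converged=converged,
        settings=settings,
        prior=prior,
        _data=data,
    )
    acc = _per_participant_accuracy(fit)
    fit.summary["predictive_accuracy"] = acc
    flags = detect_random_responders(fit)
    fit.summary["random_responder"] = flags
    return fit


def _point_probabilities(fit: GroupFit) -> np.ndarray:
    """p(LL) per (participant, trial) at posterior-mean parameter values."""
    s = fit.summary
    k = np.exp(s["logk_mean"].to_numpy())[:, None]
    data = fit._data
    dsv = data["A_ll"] / (1.0 + k * data["D_ll"]) - data["A_ss"] / (1.0 + k * data["D_ss"])
    eps = s["epsilon_mean"].to_numpy()[:, None]
    alpha = s["alpha_mean"].to_numpy()[:, None]
    return eps + (1.0 - 2.0 * eps) * ndtr(dsv / alpha)


def _per_participant_accuracy(fit: GroupFit) -> np.ndarray:
    p = _point_probabilities(fit)
    data = fit._data
    pred = (p > 0.5).astype(float)  # ties (p == 0.5) predict SS
    hits = ((pred == data["y"]) * data["mask"]).sum(axis=1)
    n = data["mask"].sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, hits / np.maximum(n, 1), np.nan)


def classify_choices(fit: GroupFit) -> float:
    """In-sample classification accuracy pooled over participants.

    A trial is predicted LL iff the fitted p(LL) at posterior-mean
    parameters exceeds 0.5 (exact ties predict SS).
    """
    p = _point_probabilities(fit)
    data = fit._data
    pred = (p > 0.5).astype(float)
    hits = ((pred == data["y"]) * data["mask"]).sum()
    return float(hits / data["mask"].sum())


def detect_random_responders(
    fit: GroupFit,
    epsilon_threshold: float = 0.25,
    accuracy_threshold: float = 0.55,
) -> np.ndarray:
    """Flag participants whose fit indicates chance-level responding.

    A participant is flagged when the posterior median lapse rate is at or
    above ``epsilon_threshold`` (half the maximal 0.5, i.e. mostly random)
    OR the model's in-sample predictive accuracy for that participant is at
    or below ``accuracy_threshold`` (barely above coin-flipping).  Flagged
    participants are excluded from downstream group statistics.
    """
    eps_med = fit.summary["epsilon_median"].to_numpy()
    acc = (
        fit.summary["predictive_accuracy"].to_numpy()
        if "predictive_accuracy" in fit.summary
        else _per_participant_accuracy(fit)
    )
    with np.errstate(invalid="ignore"):
        return (eps_med >= epsilon_threshold) | (np.nan_to_num(acc, nan=1.0) <= accuracy_threshold)
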
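"""Group comparisons, covariate-adjusted models, and bootstrap mediation.

Primary hypotheses (lower log(k) and higher future orientation in the
high-risk group) are directional and tested with one-tailed pooled-variance
t-tests; exploratory contrasts are two-tailed.  Continuous associations use
Pearson correlations.  Covariate control uses an ANCOVA (type-II F test for
the group term).  Whether future orientation statistically mediates the
group difference in log(k) is assessed with OLS path models and a
percentile bootstrap of the partial standardized indirect effect: paths are
estimated with the outcome z-scored and a binary predictor kept on its 0/1
scale, so the indirect effect a*b is in outcome-SD units per group
contrast.  Parallel-mediator models estimate all b paths jointly in a
single outcome regression and report one indirect effect per mediator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    tail: str                    # "one" or "two"
    effect_size: float | None = None
    effect_size_label: str = "d"
    kind: str = "t"

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tail": self.tail,
            self.effect_size_label: self.effect_size,
        }


@dataclass
class MediationResult:
    paths: pd.DataFrame          # per-mediator a/b paths and indirect CI
    total: dict                  # c: Y ~ X (+cov)
    direct: dict                 # c': Y ~ X + M (+cov)
    indirect_total: float
    n_boot: int
    seed: int
    n: int
    ci_level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "paths": self.paths.to_dict(orient="index"),
            "total": self.total,
            "direct": self.direct,
            "indirect_total": self.indirect_total,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
            "ci_level": self.ci_level,
        }


def group_ttest(values, group_labels, tail: str = "two", order=None) -> TestResult:
    """Pooled-variance independent-samples t-test between two groups.

    The contrast is ``mean(first) - mean(second)`` with the group order
    taken from ``order`` (or sorted labels).  With ``tail="one"`` the
    first-listed group is hypothesized to have the *smaller* mean (so pass
    ``order=("high", "low")`` for the discounting hypothesis and
    ``order=("low", "high")`` for the future-orientation one).  Effect size
    is Cohen's d on the pooled SD (the "dz" reported for between-group
    contrasts).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = list(order) if order is not None else sorted(pd.unique(group_labels))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values[group_labels == labels[0]]
    b = values[group_labels == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "less" if tail == "one" else "two-sided"
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    pooled_sd = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    return TestResult(float(t), float(df), float(p), tail, float(d), "d", "t")


def pearson_correlation(x, y, tail: str = "two") -> TestResult:
    """Pearson product-moment correlation with its t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired observations with n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance: correlation undefined")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "less" if tail == "one" else "two-sided"
    res = stats.pearsonr(x, y, alternative=alternative)
    return TestResult(
        float(res.statistic), float(len(x) - 2), float(res.pvalue),
        tail, float(res.statistic), "r", "pearson",
    )


def ancova_group_effect(outcome, group, covariates: pd.DataFrame) -> TestResult:
    """Type-II F test for the group term with covariates in a linear model."""
    df = pd.DataFrame({"outcome": np.asarray(outcome, float), "group": np.asarray(group)})
    cov_names = []
    for name in covariates.columns:
        clean = str(name).replace(" ", "_")
        df[clean] = covariates[name].to_numpy()
        cov_names.append(clean)

    X = pd.get_dummies(df[["group"] + cov_names], drop_first=True).astype(float)
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = [
            c for c in X.columns
            if np.linalg.matrix_rank(Xc.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    formula = "outcome ~ C(group)" + "".join(f" + {c}" for c in cov_names)
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(group)"]
    return TestResult(
        float(row["F"]), float(row["df"]), float(row["PR(>F)"]),
        "two", None, "d", "F",
    )


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept prepended; returns (coefs, se, t, p) excluding it."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design in path model")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - A.shape[1]
    if dof <= 0:
        raise ValueError("not enough rows for the path model")
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta[1:], se[1:], t[1:], p[1:]


def _indirects(y_raw, X, M, C, idx=None):
    """a_j * b_j per mediator with Y z-scored within the (re)sample."""
    if idx is not None:
        y_raw, X, M = y_raw[idx], X[idx], M[idx]
        C = C[idx] if C is not None else None
    sd = y_raw.std(ddof=1)
    if sd == 0:
        return np.full(M.shape[1], np.nan)
    y = (y_raw - y_raw.mean()) / sd
    cov_block = C if C is not None else np.empty((len(y), 0))
    n = len(y)
    ones = np.ones((n, 1))
    # b paths: joint outcome model Y ~ X + M (+C)
    A = np.hstack([ones, X[:, None], M, cov_block])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    b = beta[2 : 2 + M.shape[1]]
    # a paths: M_j ~ X (+C)
    Am = np.hstack([ones, X[:, None], cov_block])
    gam = np.linalg.lstsq(Am, M, rcond=None)[0]
    a = gam[1]
    return a * b


def mediate(
    X,
    M,
    Y,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """OLS mediation with a percentile bootstrap on the indirect effect(s).

    ``X`` is the (typically binary 0/1 group) predictor, ``M`` one mediator
    or a DataFrame of parallel mediators, ``Y`` the outcome.  All paths are
    estimated with Y z-scored on the analysis sample and X on its original
    scale (the "partial standardized" convention); within each bootstrap
    resample Y is re-standardized on that resample.  The OLS decomposition
    ``c = c' + sum_j a_j b_j`` holds exactly for every fitted dataset.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(M, pd.DataFrame):
        med_names = list(M.columns)
        Mm = M.to_numpy(dtype=float)
    else:
        Mm = np.asarray(M, dtype=float)
        if Mm.ndim == 1:
            Mm = Mm[:, None]
        med_names = [f"M{j + 1}" for j in range(Mm.shape[1])]
    Y = np.asarray(Y, dtype=float)
    C = covariates.to_numpy(dtype=float) if covariates is not None else None
    n = len(Y)
    if len(X) != n or Mm.shape[0] != n:
        raise ValueError("X, M and Y must have equal length")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    for j, name in enumerate(med_names):
        if Mm[:, j].std(ddof=1) == 0:
            raise ValueError(f"mediator {name!r} is constant")

    sd_y = Y.std(ddof=1)
    if sd_y == 0:
        raise ValueError("outcome is constant")
    y_z = (Y - Y.mean()) / sd_y
    cov_block = C if C is not None else np.empty((n, 0))

    # point estimates
    a_path = [
        _ols(Mm[:, j], np.column_stack([X, *cov_block.T]) if cov_block.size else X[:, None])
        for j in range(Mm.shape[1])
    ]
    design_b = np.hstack([X[:, None], Mm, cov_block])
    b_beta, b_se, b_t, b_p = _ols(y_z, design_b)
    design_c = np.hstack([X[:, None], cov_block])
    c_beta, c_se, c_t, c_p = _ols(y_z, design_c)

    a = np.array([ap[0][0] for ap in a_path])
    b = b_beta[1 : 1 + Mm.shape[1]]
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, Mm.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[i] = _indirects(Y, X, Mm, C, idx)
    lo_q = 100 * (1 - ci_level) / 2
    ci_lo = np.nanpercentile(boot, lo_q, axis=0)
    ci_hi = np.nanpercentile(boot, 100 - lo_q, axis=0)
    boot_se = np.nanstd(boot, axis=0, ddof=1)

    paths = pd.DataFrame(
        {
            "a": a,
            "a_se": [ap[1][0] for ap in a_path],
            "a_t": [ap[2][0] for ap in a_path],
            "a_p": [ap[3][0] for ap in a_path],
            "b": b,
            "b_se": b_se[1 : 1 + Mm.shape[1]],
            "b_t": b_t[1 : 1 + Mm.shape[1]],
            "b_p": b_p[1 : 1 + Mm.shape[1]],
            "indirect": indirect,
            "boot_se": boot_se,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
        },
        index=med_names,
    )
    total = {"beta": float(c_beta[0]), "se": float(c_se[0]),
             "t": float(c_t[0]), "p": float(c_p[0])}
    direct = {"beta": float(b_beta[0]), "se": float(b_se[0]),
              "t": float(b_t[0]), "p": float(b_p[0])}
    return MediationResult(
        paths=paths, total=total, direct=direct,
        indirect_total=float(indirect.sum()),
        n_boot=n_boot, seed=seed, n=n, ci_level=ci_level,
    )
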
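"""Associations between topic composition and host characteristics.

Per-participant mean topic proportions are regressed on race, pregnancy
status and study site with a Dirichlet regression (common parameterization,
α_k = exp(X b_k), log link), and on preterm birth with one logistic
regression per topic (joint fits are rank-deficient under the sum-to-one
constraint).  Exact zeros are removed with the standard simplex compression
y′ = (y·(n−1) + 1/K)/n before the Dirichlet fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_model import DataError


def participant_topic_means(
    gamma: np.ndarray, participants: list[str], topic_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-participant arithmetic mean of γ rows, renormalized to sum to 1."""
    gamma = np.asarray(gamma, dtype=float)
    if len(participants) != gamma.shape[0]:
        raise DataError("one participant id per γ row required")
    cols = topic_ids or [f"T{k + 1}" for k in range(gamma.shape[1])]
    df = pd.DataFrame(gamma, columns=cols)
    df["participant"] = list(participants)
    means = df.groupby("participant", sort=False).mean()
    means = means.div(means.sum(axis=1), axis=0)
    return means


def compress_zeros(y: np.ndarray) -> np.ndarray:
    """Simplex compression y′ = (y(n−1) + 1/K)/n: maps [0,1] proportions into (0,1).

    Bijective on the open simplex and row-sum preserving.
    """
    y = np.asarray(y, dtype=float)
    n, K = y.shape
    return (y * (n - 1) + 1.0 / K) / n


@dataclass
class DirichletFit:
    """Dirichlet regression fit: one coefficient block per topic (log link)."""

    topic_ids: list[str]
    term_names: list[str]
    coef: np.ndarray  # (K, p)
    se: np.ndarray  # (K, p)
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, topic in enumerate(self.topic_ids):
            for j, term in enumerate(self.term_names):
                rows.append({"topic": topic, "term": term, "coef": self.coef[k, j],
                             "se": self.se[k, j], "z": self.z[k, j], "p": self.p[k, j]})
        return pd.DataFrame(rows)


def _dirichlet_negll_grad(b_flat: np.ndarray, X: np.ndarray, Y: np.ndarray):
    n, p = X.shape
    K = Y.shape[1]
    B = b_flat.reshape(K, p)
    A = np.exp(np.clip(X @ B.T, -30, 30))  # (n, K)
    a0 = A.sum(axis=1)
    ll = (special.gammaln(a0).sum() - special.gammaln(A).sum()
          + ((A - 1) * np.log(Y)).sum())
    inner = special.digamma(a0)[:, None] - special.digamma(A) + np.log(Y)  # (n, K)
    grad = (A * inner).T @ X  # (K, p)
    return -ll, -grad.ravel()


def fit_dirichlet_regression(
    y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    topic_ids: list[str] | None = None,
    term_names: list[str] | None = None,
) -> DirichletFit:
    """Maximum-likelihood Dirichlet regression with α_k = exp(X b_k).

    ``X`` must include the intercept column.  Zeros in ``y`` are removed by
    simplex compression.  Wald tests use the inverse observed information
    (numerical Hessian at the optimum).  Non-convergence is flagged, never
    silent.
    """
    if isinstance(y, pd.DataFrame):
        topic_ids = topic_ids or [str(c) for c in y.columns]
        y = y.to_numpy()
    if isinstance(X, pd.DataFrame):
        term_names = term_names or [str(c) for c in X.columns]
        X = X.to_numpy()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, K = y.shape
    p = X.shape[1]
    if K < 2:
        raise DataError("Dirichlet regression requires K ≥ 2 components")
    if np.linalg.matrix_rank(X) < p:
        raise DataError("design matrix is rank deficient")
    topic_ids = topic_ids or [f"T{k + 1}" for k in range(K)]
    term_names = term_names or [f"x{j}" for j in range(p)]
    Y = compress_zeros(y)
    Y = Y / Y.sum(axis=1, keepdims=True)

    # moment-matched start: common precision from mean/variance, zero slopes
    m = Y.mean(axis=0)
    v = Y.var(axis=0).mean()
    prec = max((m * (1 - m)).mean() / max(v, 1e-8) - 1, 1.0)
    B0 = np.zeros((K, p))
    B0[:, 0] = np.log(np.maximum(m * prec, 1e-6))
    start_nll, _ = _dirichlet_negll_grad(B0.ravel(), X, Y)

    res = optimize.minimize(
        _dirichlet_negll_grad, B0.ravel(), args=(X, Y), jac=True,
        method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    B = res.x.reshape(K, p)
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(res.x, lambda b: _dirichlet_negll_grad(b, X, Y)[0])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(K, p)
        ok = True
    except np.linalg.LinAlgError:
        se = np.full((K, p), np.nan)
        ok = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, B / np.where(se > 0, se, 1.0), np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return DirichletFit(
        topic_ids=topic_ids,
        term_names=term_names,
        coef=B,
        se=se,
        z=z,
        p=pvals,
        log_likelihood=float(-res.fun),
        converged=bool(res.success and ok and -res.fun >= -start_nll - 1e-6),
    )


def build_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-participant design: intercept + race (Black/White vs Other) + pregnancy + site."""
    per_p = meta.groupby("participant").first()
    X = pd.DataFrame(index=per_p.index)
    X["intercept"] = 1.0
    X["race_Black"] = (per_p["race"] == "Black").astype(float)
    X["race_White"] = (per_p["race"] == "White").astype(float)
    X["pregnant"] = per_p["pregnant"].astype(float)
    X["site_SU"] = (per_p["cohort"] == "P-SU").astype(float)
    return X


def test_preterm(
    avg_topics: pd.DataFrame, preterm: pd.Series, min_n: int = 10
) -> pd.DataFrame:
    """Per-topic logistic regression of preterm birth on average topic proportion.

    One univariate fit per topic (outcome ~ intercept + proportion) avoids the
    sum-to-one rank deficiency of a joint fit; p-values BH-adjusted across
    topics.  Refuses to fit with fewer than ``min_n`` participants or a
    constant outcome.
    """
    import statsmodels.api as sm
    from .assays import bh_adjust

    common = avg_topics.index.intersection(preterm.dropna().index)
    yy = preterm.loc[common].astype(int)
    if len(common) < min_n:
        raise DataError(f"need at least {min_n} participants with outcomes; got {len(common)}")
    if yy.nunique() < 2:
        raise DataError("preterm outcome is constant")
    rows = []
    for topic in avg_topics.columns:
        Xt = sm.add_constant(avg_topics.loc[common, topic].to_numpy())
        try:
            fit = sm.Logit(yy.to_numpy(), Xt).fit(disp=0, maxiter=200)
            rows.append({"topic": topic, "coef": fit.params[1], "se": fit.bse[1],
                         "p": fit.pvalues[1]})
        except Exception:  # separation etc.: report without inference
            rows.append({"topic": topic, "coef": np.nan, "se": np.nan, "p": np.nan})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[valid, "p_adj"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out
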
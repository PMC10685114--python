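"""Metabolite and cytokine table preprocessing and cyclicity testing.

Metabolite relative concentrations arrive with heavy missingness: features
missing in >50% of samples are dropped, then samples missing >60% of the
remaining features, and kept values are variance-stabilized with a glog
transform.  Cytokine concentrations are censored at the assay's limits of
quantification: below-LLOQ values are imputed at LLOQ/2, above-ULOQ values at
ULOQ, technical replicates are combined by their median after imputation, and
concentrations are natural-log transformed.

Cycle-dependence of a feature is tested by regressing it on a periodic cubic
B-spline basis over the standardized 26-day cycle (day −18 … +7, day 0 = first
day of menses) and comparing against an intercept-only model; p-values are
Benjamini–Hochberg adjusted across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .data_model import DataError

CYCLE_PERIOD = 26
CYCLEDAY_MIN, CYCLEDAY_MAX = -18, 7


@dataclass
class AssayMatrix:
    """Samples × features concentrations with missingness and LOQ bounds."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # NaN = missing
    lloq: np.ndarray | None = None  # per-feature lower limit of quantification
    uloq: np.ndarray | None = None
    transform: str = "raw"  # one of {raw, glog, log}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataError("assay matrix shape mismatch")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def glog(x: np.ndarray, c: float | np.ndarray) -> np.ndarray:
    """Generalized log transform log2((x + sqrt(x² + c)) / 2); → log2(x) as c → 0."""
    return np.log2((x + np.sqrt(x**2 + c)) / 2.0)


def preprocess_metabolites(
    raw: AssayMatrix,
    feature_missing_max: float = 0.5,
    sample_missing_max: float = 0.6,
) -> AssayMatrix:
    """Filter by missingness (features strictly >50%, then samples strictly >60%)
    and glog-transform the kept values.

    The glog offset c is per-feature: the squared 5th percentile of that
    feature's positive observed values.  Remaining missing cells stay missing.
    """
    if raw.transform != "raw":
        raise DataError("metabolite preprocessing expects raw concentrations")
    vals = raw.values.copy()
    f_missing = np.isnan(vals).mean(axis=0)
    keep_f = f_missing <= feature_missing_max
    if not keep_f.any():
        raise DataError("all metabolite features exceeded the missingness limit")
    vals = vals[:, keep_f]
    feature_ids = [f for f, k in zip(raw.feature_ids, keep_f) if k]
    s_missing = np.isnan(vals).mean(axis=1)
    keep_s = s_missing <= sample_missing_max
    vals = vals[keep_s]
    sample_ids = [s for s, k in zip(raw.sample_ids, keep_s) if k]
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        pos = obs[obs > 0]
        c = float(np.percentile(pos, 5)) ** 2 if pos.size else 0.0
        m = ~np.isnan(col)
        out[m, j] = glog(col[m], c)
    return AssayMatrix(sample_ids, feature_ids, out, transform="glog")


def preprocess_cytokines(
    raw: AssayMatrix,
    replicates: Mapping[str, Sequence[str]] | None = None,
) -> AssayMatrix:
    """Impute censored cytokine values, combine replicates, log-transform.

    Below-LLOQ → LLOQ/2; above-ULOQ → ULOQ; medians of technical replicates
    taken after imputation (``replicates`` maps an output sample id to its
    replicate sample ids); assay failures (NaN) stay missing.
    """
    if raw.lloq is None or raw.uloq is None:
        raise DataError("cytokine preprocessing requires LLOQ and ULOQ bounds")
    if np.any(raw.lloq >= raw.uloq):
        raise DataError("LLOQ must be below ULOQ for every feature")
    vals = raw.values.copy()
    below = vals < raw.lloq[None, :]
    above = vals > raw.uloq[None, :]
    vals = np.where(below, raw.lloq[None, :] / 2.0, vals)
    vals = np.where(above, np.broadcast_to(raw.uloq, vals.shape), vals)
    if replicates:
        idx = {s: i for i, s in enumerate(raw.sample_ids)}
        out_ids = list(replicates.keys())
        merged = np.full((len(out_ids), vals.shape[1]), np.nan)
        for i, out_id in enumerate(out_ids):
            rows = vals[[idx[r] for r in replicates[out_id]]]
            with np.errstate(all="ignore"):
                merged[i] = np.nanmedian(rows, axis=0)
        vals, sample_ids = merged, out_ids
    else:
        sample_ids = list(raw.sample_ids)
    with np.errstate(invalid="ignore"):
        vals = np.log(vals)
    return AssayMatrix(sample_ids, list(raw.feature_ids), vals,
                       lloq=raw.lloq, uloq=raw.uloq, transform="log")


# ---------------------------------------------------------------------------
# Cyclicity testing


def circular_basis(cycleday: np.ndarray, df: int = 4) -> np.ndarray:
    """Periodic cubic B-spline basis on the 26-day cycle (−18 adjacent to +7).

    Returns a (n, df) matrix; basis functions are C²-continuous across the
    wrap point and form a partition of unity, so together with an intercept
    the design has rank df.
    """
    if df < 3:
        raise DataError("df must be ≥ 3")
    cycleday = np.asarray(cycleday, dtype=float)
    # +8 is accepted as the wrap of −18 (one full period past day +7)
    if np.any(cycleday < CYCLEDAY_MIN) or np.any(cycleday > CYCLEDAY_MAX + 1):
        raise DataError(f"cycledays must lie in [{CYCLEDAY_MIN}, {CYCLEDAY_MAX}]")
    x = np.mod(cycleday - CYCLEDAY_MIN, CYCLE_PERIOD)
    period = float(CYCLE_PERIOD)
    degree = 3
    step = period / df
    knots = step * np.arange(-degree, df + degree + 1)
    design = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    # fold wrapped columns: basis j ≡ j mod df
    basis = np.zeros((len(x), df))
    for j in range(design.shape[1]):
        basis[:, j % df] += design[:, j]
    return basis


def test_cyclicity(
    values: np.ndarray,
    cycledays: np.ndarray,
    kind: str = "continuous",
    df: int = 4,
) -> tuple[float, float]:
    """Test one feature for cycle-dependence; returns (statistic, p).

    continuous: OLS of the (already transformed) values on intercept +
    circular basis, F-test against the intercept-only model.  proportion:
    quasi-binomial regression of proportions in [0,1], scaled likelihood-ratio
    chi-square against intercept-only.  A constant response gives p = 1.
    """
    values = np.asarray(values, dtype=float)
    cycledays = np.asarray(cycledays)
    keep = ~np.isnan(values)
    values, cycledays = values[keep], cycledays[keep]
    if len(np.unique(cycledays)) < 8:
        raise DataError("cyclicity test requires ≥ 8 distinct cycledays")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    basis = circular_basis(cycledays, df=df)
    # drop one redundant column: the basis sums to 1, collinear with intercept
    X = np.column_stack([np.ones(len(values)), basis[:, :-1]])
    q = X.shape[1] - 1
    if kind == "continuous":
        import statsmodels.api as sm

        fit1 = sm.OLS(values, X).fit()
        fit0 = sm.OLS(values, X[:, :1]).fit()
        num = (fit0.ssr - fit1.ssr) / q
        den = fit1.ssr / fit1.df_resid
        if den == 0:
            return float("inf"), 0.0
        F = num / den
        p = float(stats.f.sf(F, q, fit1.df_resid))
        return float(F), p
    if kind == "proportion":
        import statsmodels.api as sm

        eps = 1e-6
        y = np.clip(values, eps, 1 - eps)
        fam = sm.families.Binomial()
        fit1 = sm.GLM(y, X, family=fam).fit(scale="X2")
        fit0 = sm.GLM(y, X[:, :1], family=fam).fit(scale="X2")
        lr = (fit0.deviance - fit1.deviance) / fit1.scale
        lr = max(lr, 0.0)
        p = float(stats.chi2.sf(lr, q))
        return float(lr), p
    raise DataError(f"unknown kind {kind!r}")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def test_cyclicity_batch(
    assay: AssayMatrix,
    cycledays: np.ndarray,
    kind: str = "continuous",
    df: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature cyclicity tests with BH adjustment and significance stars."""
    stats_, pvals = [], []
    for j in range(len(assay.feature_ids)):
        s, p = test_cyclicity(assay.values[:, j], cycledays, kind=kind, df=df)
        stats_.append(s)
        pvals.append(p)
    p_adj = bh_adjust(np.asarray(pvals))
    stars = np.where(p_adj < 0.001, "***", np.where(p_adj < 0.01, "**", np.where(p_adj < alpha, "*", "")))
    return pd.DataFrame(
        {"feature": assay.feature_ids, "statistic": stats_, "p": pvals,
         "p_adj": p_adj, "significant": p_adj < alpha, "stars": stars}
    )
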
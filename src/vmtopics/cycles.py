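"""Menstrual-cycle identification, cycleday standardization and cycle agreement.

Menses are segmented from daily bleeding diaries (scores 0–3) with a two-state
explicit-duration hidden semi-Markov model (Menses / InterMenses) decoded by
Viterbi.  Cycledays are standardized to −18…+7: menses days count forward from
each onset (day 0 = first day of menses, up to +7) and late-luteal days count
backward from the *next* onset (−18…−1), following the convention that the
luteal phase varies less in duration than the follicular phase.

Between-cycle agreement of a participant's composition (topics or taxa) is
measured by the RV coefficient with a row-permutation test; within-cycle
change is the maximum pairwise Bray–Curtis dissimilarity among per-cycleday
mean compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError
from .reference import bray_curtis

CYCLEDAY_MIN, CYCLEDAY_MAX = -18, 7


def _discretized_normal(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Pmf over integer durations lo..hi from a discretized normal."""
    d = np.arange(lo, hi + 1)
    if sd <= 0:
        pmf = (d == int(round(mean))).astype(float)
        if pmf.sum() == 0:
            raise DataError("degenerate duration outside support")
    else:
        pmf = stats.norm.pdf(d, loc=mean, scale=sd)
    return pmf / pmf.sum()


@dataclass
class HsmmParams:
    """Two-state explicit-duration HMM for bleeding diaries.

    Emissions are per-state distributions over scores 0–3; sojourn pmfs are
    over 1–10 days (Menses) and 5–80 days (InterMenses).
    """

    menses_emission: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 0.3, 0.4, 0.2])
    )
    inter_emission: np.ndarray = field(
        default_factory=lambda: np.array([0.95, 0.05, 0.0, 0.0])
    )
    menses_duration: np.ndarray = field(
        default_factory=lambda: _discretized_normal(4.0, 1.5, 1, 10)
    )
    inter_duration: np.ndarray = field(
        default_factory=lambda: _discretized_normal(24.0, 4.0, 5, 80)
    )
    menses_dur_lo: int = 1
    inter_dur_lo: int = 5

    def __post_init__(self) -> None:
        for name, arr in (
            ("menses_emission", self.menses_emission),
            ("inter_emission", self.inter_emission),
            ("menses_duration", self.menses_duration),
            ("inter_duration", self.inter_duration),
        ):
            arr = np.asarray(arr, dtype=float)
            if not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise DataError(f"{name} must sum to 1 within 1e-9")
            setattr(self, name, arr)


def screen_diary(diary: np.ndarray, study_days: int = 70) -> tuple[bool, str | None]:
    """Inclusion screen: exclude diaries with <3 or >30 bleeding days (score ≥ 1)."""
    diary = np.asarray(diary)
    if np.any((diary < 0) | (diary > 3)):
        raise DataError("bleeding scores must lie in 0..3")
    n_bleed = int((diary[:study_days] >= 1).sum())
    if n_bleed < 3:
        return False, "too few bleeding days"
    if n_bleed > 30:
        return False, "too many bleeding days"
    return True, None


def identify_cycles(diary: np.ndarray, params: HsmmParams | None = None) -> list[int]:
    """Menses onset days from explicit-duration Viterbi decoding.

    The final segment of the decoding may be censored by the end of the diary
    (survival instead of pmf mass); isolated spotting days, which the
    InterMenses state can emit, do not open a cycle.  Returns the first day of
    each decoded Menses segment; an empty list means no cycle was identified.
    """
    params = params or HsmmParams()
    diary = np.asarray(diary, dtype=int)
    T = len(diary)
    # moderate log-zero: large enough to forbid, small enough that cumulative
    # sums keep full float precision for the feasible parts of a path
    LOG0 = -1e4

    def logp(a: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(a > 0, np.log(np.maximum(a, 1e-300)), LOG0)

    em = [logp(params.menses_emission)[diary], logp(params.inter_emission)[diary]]
    cum_em = [np.concatenate([[0.0], np.cumsum(e)]) for e in em]
    durations = []  # per state: (lo, hi, log pmf, log survival over observed d=1..hi)
    for lo, pmf in (
        (params.menses_dur_lo, params.menses_duration),
        (params.inter_dur_lo, params.inter_duration),
    ):
        hi = lo + len(pmf) - 1
        # P(D ≥ d) for observed duration d = 1..hi (1 below the support minimum)
        tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        sf = np.array([1.0 if d < lo else tail[d - lo] for d in range(1, hi + 1)])
        durations.append((lo, hi, logp(np.asarray(pmf)), logp(sf)))

    # V[t][s]: best log-prob of a segmentation of days 0..t-1 ending with a
    # segment of state s at day t-1.  back[t][s] = (duration, previous state).
    # Segments truncated by either diary edge use survival mass P(D ≥ d).
    V = np.full((T + 1, 2), LOG0)
    back = np.zeros((T + 1, 2, 2), dtype=int)
    for t in range(1, T + 1):
        for s, (lo, hi, lpmf, lsf) in enumerate(durations):
            best, arg = LOG0, (0, 0)
            for d in range(1, min(hi, t) + 1):
                censored = (t == T) or (t - d == 0)
                if d < lo and not censored:
                    continue
                e = cum_em[s][t] - cum_em[s][t - d]
                dur_mass = lsf[d - 1] if censored else lpmf[d - lo]
                if t - d == 0:
                    cand = e + dur_mass  # either state may start the diary
                    if cand > best:
                        best, arg = cand, (d, -1)
                else:
                    cand = e + dur_mass + V[t - d][1 - s]
                    if cand > best:
                        best, arg = cand, (d, 1 - s)
            V[t][s] = best
            back[t][s] = arg
    # backtrack; any segmentation using a forbidden emission/duration scores
    # below -LOG0/2 and is treated as "no decoding"
    s = int(np.argmax(V[T]))
    if V[T][s] <= LOG0 / 2:
        return []
    t = T
    segments = []
    while t > 0:
        d, prev = back[t][s]
        segments.append((t - d, t, s))
        t -= d
        if prev == -1:
            break
        s = prev
    segments.reverse()
    # an onset is only reported when the decoded menses segment contains at
    # least one observed bleeding day — an invisible menses cannot be dated
    onsets = [start for start, end, st in segments
              if st == 0 and (diary[start:end] >= 1).any()]
    return onsets


@dataclass
class CycleTable:
    """Per-participant onsets and the sample-day → standardized-cycleday map."""

    onsets: list[int]
    table: pd.DataFrame  # columns: day, cycle_index, cycleday (nullable Int64)


def standardize_cycledays(onsets: list[int], sample_days: list[int]) -> CycleTable:
    """Map observation days to standardized cycledays in −18…+7.

    Forward index f = day − most recent onset; backward index b = day − next
    onset.  Rule: 0 ≤ f ≤ 7 → cycleday f (forward rule wins on conflict, so
    menses days are always 0…+7); else −18 ≤ b ≤ −1 → cycleday b; else null.
    Days after the last onset receive only the forward rule.
    """
    if not onsets:
        raise DataError("standardization requires at least one onset")
    onsets = sorted(onsets)
    rows = []
    for day in sample_days:
        prev = [o for o in onsets if o <= day]
        nxt = [o for o in onsets if o > day]
        f = day - prev[-1] if prev else None
        b = day - nxt[0] if nxt else None
        cycleday = None
        cycle_index = None
        if f is not None and 0 <= f <= CYCLEDAY_MAX:
            cycleday = f
            cycle_index = len(prev) - 1
        elif b is not None and CYCLEDAY_MIN <= b <= -1:
            cycleday = b
            cycle_index = len(prev)  # belongs to the upcoming cycle
        rows.append({"day": day, "cycle_index": cycle_index, "cycleday": cycleday})
    table = pd.DataFrame(rows).astype({"cycle_index": "Int64", "cycleday": "Int64"})
    return CycleTable(onsets=onsets, table=table)


# ---------------------------------------------------------------------------
# Cycle agreement and change magnitude


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV coefficient between two cycleday × feature matrices (columns centered).

    RV = tr(XXᵀYYᵀ) / √(tr((XXᵀ)²)·tr((YYᵀ)²)), computed via the identity
    tr(XXᵀYYᵀ) = ‖XᵀY‖²_F.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise DataError("X and Y must share rows (matched cycledays)")
    if X.shape[0] < 3:
        raise DataError("RV requires at least 3 shared cycledays")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = np.sum((Xc.T @ Yc) ** 2)
    den = np.sqrt(np.sum((Xc.T @ Xc) ** 2) * np.sum((Yc.T @ Yc) ** 2))
    if den == 0:
        raise DataError("degenerate (constant) matrix in RV computation")
    return float(num / den)


def rv_permutation_test(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Row-permutation test of the RV coefficient.

    p = (1 + #{RV_perm ≥ RV_obs}) / (n_perm + 1).  Returns (RV_obs, p).
    """
    rv_obs = rv_coefficient(X, Y)
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    count = 0
    for _ in range(n_perm):
        rv_p = rv_coefficient(X, Y[rng.permutation(len(Y))])
        if rv_p >= rv_obs - 1e-12:
            count += 1
    return rv_obs, (1 + count) / (n_perm + 1)


def align_cycles(
    cycledays_a: np.ndarray, values_a: np.ndarray,
    cycledays_b: np.ndarray, values_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycleday means of two cycles restricted to their shared cycledays."""
    da = pd.DataFrame(values_a).groupby(np.asarray(cycledays_a)).mean()
    db = pd.DataFrame(values_b).groupby(np.asarray(cycledays_b)).mean()
    shared = da.index.intersection(db.index)
    if len(shared) < 3:
        raise DataError("fewer than 3 shared cycledays between cycles")
    return da.loc[shared].to_numpy(), db.loc[shared].to_numpy()


def cycle_change_magnitude(cycledays: np.ndarray, compositions: np.ndarray) -> float:
    """Maximum pairwise Bray–Curtis among per-cycleday mean compositions.

    Means are taken across samples (pooling cycles) per cycleday and
    renormalized to sum to 1 before the pairwise comparison.
    """
    cycledays = np.asarray(cycledays)
    if len(np.unique(cycledays)) < 2:
        raise DataError("need at least 2 distinct cycledays")
    means = pd.DataFrame(np.asarray(compositions, dtype=float)).groupby(cycledays).mean()
    M = means.to_numpy()
    M = M / M.sum(axis=1, keepdims=True)
    best = 0.0
    for i in range(len(M)):
        for j in range(i + 1, len(M)):
            best = max(best, bray_curtis(M[i], M[j]))
    return best


def summarize_ph(
    ph: np.ndarray, dominant: np.ndarray, menses: np.ndarray
) -> pd.DataFrame:
    """Mean and central 90% interval of pH per (dominance × menses) stratum."""
    ph = np.asarray(ph, dtype=float)
    if np.any((ph < 3) | (ph > 10)):
        raise DataError("pH values must lie in [3, 10]")
    dominant = np.asarray(dominant, dtype=bool)
    menses = np.asarray(menses, dtype=bool)
    rows = []
    for dom in (True, False):
        for men in (True, False):
            sel = ph[(dominant == dom) & (menses == men)]
            if sel.size == 0:
                rows.append({"dominant": dom, "menses": men, "n": 0,
                             "mean": np.nan, "q05": np.nan, "q95": np.nan})
            else:
                rows.append({"dominant": dom, "menses": men, "n": int(sel.size),
                             "mean": float(sel.mean()),
                             "q05": float(np.percentile(sel, 5)),
                             "q95": float(np.percentile(sel, 95))})
    return pd.DataFrame(rows)
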
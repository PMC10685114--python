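"""Mixed-membership composition prediction, stability, and dominance-loss risk.

A sample's composition can be predicted either from its topic memberships
(p̂_{ij} = Σ_k γ_{ik} β_{kj}) or from its sub-CST assignment (the centroid
composition).  The Bray–Curtis dissimilarity between actual and predicted
compositions measures representation error; topics and sub-CSTs are compared
with a one-sided paired t-test.

Samples are locally *stable* when they belong to a run of five consecutive
samples whose consecutive-pair Bray–Curtis dissimilarities are all below a
threshold (default 0.25; 0.15 and 0.35 for sensitivity).

Loss of *Lactobacillus* dominance (total *Lactobacillus* proportion of the
next sample falling below 50%) is predicted from the current sample's features
(topic γ vector or one-hot sub-CST) with a class-weighted logistic regression;
performance is compared by F1 over repeated participant-grouped 80/20 splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CompositionMatrix, DataError
from .lda import TopicModelFit
from .reference import ReferenceCentroids, bray_curtis

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Composition prediction


def predict_from_topics(fit: TopicModelFit) -> CompositionMatrix:
    """Predicted composition p̂ = γ β (mixed-membership weighted topic average)."""
    values = fit.gamma @ fit.beta
    values = values / values.sum(axis=1, keepdims=True)
    return CompositionMatrix(list(fit.sample_ids), list(fit.taxon_ids), values)


def predict_from_subcst(
    labels: list[str], centroids: ReferenceCentroids, sample_ids: list[str] | None = None
) -> CompositionMatrix:
    """Predicted composition = the assigned sub-CST centroid's composition."""
    lidx = {lab: i for i, lab in enumerate(centroids.labels)}
    unknown = [lab for lab in labels if lab not in lidx]
    if unknown:
        raise DataError(f"labels not present in centroids: {sorted(set(unknown))}")
    values = centroids.values[[lidx[lab] for lab in labels]]
    values = values / values.sum(axis=1, keepdims=True)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(labels))]
    return CompositionMatrix(list(sample_ids), list(centroids.taxon_ids), values)


@dataclass
class RepresentationError:
    bc_topics: np.ndarray  # per-sample BC(actual, topic-predicted)
    bc_subcst: np.ndarray  # per-sample BC(actual, centroid-predicted)
    mean_difference: float  # mean(BC_subcst − BC_topics)
    t_statistic: float | None
    p_value: float | None  # one-sided: difference > 0


def representation_error(
    actual: CompositionMatrix,
    predicted_topics: CompositionMatrix,
    predicted_subcst: CompositionMatrix,
) -> RepresentationError:
    """Per-sample Bray–Curtis errors of both predictions plus a one-sided paired t-test.

    All three matrices must cover the same samples in the same order (taxa may
    differ between sources; each is compared with ``actual`` on its own taxa,
    which must match).  With fewer than 3 samples the t-test is refused and
    only descriptives are returned.
    """
    for pred in (predicted_topics, predicted_subcst):
        if pred.row_ids != actual.row_ids:
            raise DataError("predictions must cover the same samples as `actual`, in order")
    bc_t = _paired_bc(actual, predicted_topics)
    bc_s = _paired_bc(actual, predicted_subcst)
    diff = bc_s - bc_t
    if len(diff) < 3:
        return RepresentationError(bc_t, bc_s, float(diff.mean()), None, None)
    t, p_two = stats.ttest_rel(bc_s, bc_t)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    if np.isnan(t):  # identical arrays → zero variance of differences
        t, p_one = 0.0, 0.5
    return RepresentationError(bc_t, bc_s, float(diff.mean()), float(t), float(p_one))


def _paired_bc(a: CompositionMatrix, b: CompositionMatrix) -> np.ndarray:
    if a.taxon_ids != b.taxon_ids:
        raise DataError("actual and predicted compositions must share taxa")
    return np.array([bray_curtis(pa, pb) for pa, pb in zip(a.values, b.values)])


# ---------------------------------------------------------------------------
# Local stability


def classify_stability(
    series: CompositionMatrix,
    threshold: float = 0.25,
    window: int = 5,
) -> np.ndarray:
    """Flag each time-ordered sample of one participant stable/unstable.

    A sample is stable iff it belongs to at least one run of ``window``
    consecutive samples in which every consecutive-pair Bray–Curtis
    dissimilarity is below ``threshold``.  Participants with fewer than
    ``window`` samples are entirely unstable.
    """
    n = series.n_rows
    stable = np.zeros(n, dtype=bool)
    if n < window:
        logger.info("series of %d samples is shorter than the window (%d): all unstable", n, window)
        return stable
    pair_ok = np.array(
        [bray_curtis(series.values[i], series.values[i + 1]) < threshold for i in range(n - 1)]
    )
    for start in range(n - window + 1):
        if pair_ok[start : start + window - 1].all():
            stable[start : start + window] = True
    return stable


def classify_stability_by_participant(
    compositions: CompositionMatrix,
    participants: list[str],
    threshold: float = 0.25,
    window: int = 5,
) -> np.ndarray:
    """Apply ``classify_stability`` within each participant (samples already time-ordered)."""
    participants = list(participants)
    stable = np.zeros(compositions.n_rows, dtype=bool)
    for pid in dict.fromkeys(participants):
        idx = [i for i, p in enumerate(participants) if p == pid]
        sub = CompositionMatrix(
            [compositions.row_ids[i] for i in idx],
            list(compositions.taxon_ids),
            compositions.values[idx],
        )
        stable[idx] = classify_stability(sub, threshold=threshold, window=window)
    return stable


# ---------------------------------------------------------------------------
# Dominance-loss prediction


@dataclass
class TransitionPair:
    participant: str
    current_id: str
    next_id: str
    features_gamma: np.ndarray  # current topic proportions
    subcst_label: str | None  # current sub-CST assignment
    current_dominant: bool
    outcome_loss: bool  # next-sample Lactobacillus total < 0.5


def make_transition_pairs(
    compositions: CompositionMatrix,
    participants: list[str],
    gamma: np.ndarray,
    lactobacillus_taxa: set[str],
    subcst_labels: list[str] | None = None,
    dominance_threshold: float = 0.5,
) -> list[TransitionPair]:
    """Consecutive within-participant pairs with dominance status and loss outcome.

    ``current_dominant`` is the current sample's total *Lactobacillus*
    proportion ≥ 0.5; ``outcome_loss`` is the next sample's total < 0.5.  The
    evaluation set downstream is restricted to currently dominant pairs.
    """
    if not lactobacillus_taxa:
        raise DataError("empty Lactobacillus taxon set")
    cols = [j for j, t in enumerate(compositions.taxon_ids) if t in lactobacillus_taxa]
    if not cols:
        raise DataError("no Lactobacillus taxa found in the composition matrix")
    lacto = compositions.values[:, cols].sum(axis=1)
    pairs: list[TransitionPair] = []
    for i in range(compositions.n_rows - 1):
        if participants[i] != participants[i + 1]:
            continue
        pairs.append(
            TransitionPair(
                participant=participants[i],
                current_id=compositions.row_ids[i],
                next_id=compositions.row_ids[i + 1],
                features_gamma=np.asarray(gamma[i], dtype=float),
                subcst_label=subcst_labels[i] if subcst_labels is not None else None,
                current_dominant=bool(lacto[i] >= dominance_threshold),
                outcome_loss=bool(lacto[i + 1] < dominance_threshold),
            )
        )
    return pairs


def _feature_matrix(
    pairs: list[TransitionPair], feature_source: str, levels: list[str] | None = None
) -> np.ndarray:
    if feature_source == "topics":
        # drop one component: γ rows sum to one
        G = np.array([p.features_gamma for p in pairs])
        return G[:, :-1]
    if feature_source == "subcst":
        labels = [p.subcst_label for p in pairs]
        if any(lab is None for lab in labels):
            raise DataError("pairs lack sub-CST labels")
        if levels is None:
            levels = sorted(set(labels))
        ref = levels[0]  # reference level dropped
        return np.array([[1.0 if lab == lev else 0.0 for lev in levels if lev != ref] for lab in labels])
    raise DataError(f"unknown feature source {feature_source!r}")


def fit_dominance_model(
    pairs: list[TransitionPair],
    feature_source: str = "topics",
    minority_weight: float = 10.0,
    levels: list[str] | None = None,
):
    """Weighted maximum-likelihood logistic regression of loss on current features.

    The minority class (dominance loss) receives ``minority_weight``-fold
    sample weight.  Effectively unpenalized (C → ∞).  Returns a fitted
    scikit-learn classifier.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.array([p.outcome_loss for p in pairs], dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("training pairs contain a single outcome class")
    X = _feature_matrix(pairs, feature_source, levels)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    w = np.where(y == minority, minority_weight, 1.0)
    model = LogisticRegression(C=1e10, solver="lbfgs", max_iter=5000, tol=1e-10)
    model.fit(X, y, sample_weight=w)
    return model


def f1_score_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2PR/(P+R); 0 by convention when there are no positive predictions."""
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def evaluate_dominance(
    pairs: list[TransitionPair],
    n_repeats: int = 10,
    train_fraction: float = 0.8,
    minority_weight: float = 10.0,
    seed: int = 0,
    restrict_to_dominant: bool = True,
) -> pd.DataFrame:
    """Repeated participant-grouped 80/20 evaluation of both feature sources.

    Splits are by participant (all of a participant's pairs land on one side);
    both sources are evaluated on identical splits.  Returns one row per
    (repeat, source) with F1 and precision; repeats whose test split has no
    positive outcome are flagged ``valid=False`` and excluded from the
    Wilcoxon comparison by :func:`compare_dominance_sources`.
    """
    if restrict_to_dominant:
        pairs = [p for p in pairs if p.current_dominant]
    participants = sorted({p.participant for p in pairs})
    if len(participants) < 2:
        raise DataError("need pairs from at least 2 participants")
    levels = (sorted({p.subcst_label for p in pairs})
              if all(p.subcst_label is not None for p in pairs) else None)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(len(participants))
        n_train = max(1, int(round(train_fraction * len(participants))))
        train_p = {participants[i] for i in perm[:n_train]}
        train = [p for p in pairs if p.participant in train_p]
        test = [p for p in pairs if p.participant not in train_p]
        y_test = np.array([p.outcome_loss for p in test], dtype=int)
        valid = bool(len(test) > 0 and y_test.any())
        train_classes = {p.outcome_loss for p in train}
        if len(train_classes) < 2:
            valid = False
        for source in ("topics", "subcst"):
            if not valid:
                rows.append({"repeat": rep, "source": source, "f1": np.nan,
                             "precision": np.nan, "valid": False})
                continue
            model = fit_dominance_model(train, source, minority_weight, levels=levels)
            yhat = model.predict(_feature_matrix(test, source, levels))
            tp = int(((yhat == 1) & (y_test == 1)).sum())
            fp = int(((yhat == 1) & (y_test == 0)).sum())
            fn = int(((yhat == 0) & (y_test == 1)).sum())
            precision = tp / (tp + fp) if tp + fp else 0.0
            rows.append({"repeat": rep, "source": source,
                         "f1": f1_score_from_counts(tp, fp, fn),
                         "precision": precision, "valid": True})
        if not valid:
            logger.info("repeat %d excluded: test split without both classes", rep)
    return pd.DataFrame(rows)


def compare_dominance_sources(results: pd.DataFrame) -> dict:
    """Wilcoxon rank-sum comparison of per-repeat F1 between feature sources."""
    ok = results[results["valid"]]
    f1_t = ok.loc[ok["source"] == "topics", "f1"].to_numpy()
    f1_s = ok.loc[ok["source"] == "subcst", "f1"].to_numpy()
    stat, p = stats.ranksums(f1_t, f1_s)
    return {
        "median_f1_topics": float(np.median(f1_t)),
        "median_f1_subcst": float(np.median(f1_s)),
        "n_repeats_topics_higher": int((f1_t > f1_s).sum()),
        "n_valid_repeats": int(len(f1_t)),
        "wilcoxon_statistic": float(stat),
        "p_value": float(p),
    }
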
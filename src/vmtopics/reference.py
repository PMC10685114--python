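"""Comparison of topics and samples with reference sub-CST centroids.

Reference community state type (CST) centroids — e.g. the Valencia sub-CST
centroids I-A…IV-C4, V — are compositions over a harmonized taxonomy.  Topics
are labelled by their nearest centroid under Bray–Curtis dissimilarity (with
the sub-level letter collapsed to the CST family), and samples are assigned to
the centroid maximizing the Yue–Clayton similarity θ.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CompositionMatrix, DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Similarity measures


def bray_curtis(p: np.ndarray, q: np.ndarray) -> float:
    """Bray–Curtis dissimilarity 1 − Σ_j min(p_j, q_j) for compositions.

    Computed via the equivalent ½·Σ|p_j − q_j| form, which is exactly zero at
    p = q instead of inheriting the row-sum rounding of 1 − Σ min.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DataError(f"mismatched taxa: {p.shape} vs {q.shape}")
    return float(0.5 * np.abs(p - q).sum())


def yue_clayton(p: np.ndarray, q: np.ndarray) -> float:
    """Yue–Clayton similarity θ = Σpq / (Σp² + Σq² − Σpq)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DataError(f"mismatched taxa: {p.shape} vs {q.shape}")
    pq = float(np.dot(p, q))
    return pq / (float(np.dot(p, p)) + float(np.dot(q, q)) - pq)


# ---------------------------------------------------------------------------
# Reference centroids


@dataclass
class ReferenceCentroids:
    """Sub-CST centroid compositions plus the taxon harmonization map."""

    labels: list[str]
    taxon_ids: list[str]
    values: np.ndarray  # (n_labels, n_taxa) row-stochastic
    harmonization: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.taxon_ids)):
            raise DataError("centroid matrix shape mismatch")
        if not np.allclose(self.values.sum(1), 1.0, atol=1e-6):
            raise DataError("centroid rows must sum to 1 (tolerance 1e-6)")

    @property
    def composition(self) -> CompositionMatrix:
        v = self.values / self.values.sum(1, keepdims=True)
        return CompositionMatrix(list(self.labels), list(self.taxon_ids), v)

    @classmethod
    def from_csv(cls, path: str | Path, harmonization: Mapping[str, str] | None = None) -> "ReferenceCentroids":
        """Read centroids from long-format CSV: columns label, taxon, proportion."""
        df = pd.read_csv(path)
        need = {"label", "taxon", "proportion"}
        if not need.issubset(df.columns):
            raise DataError(f"centroid CSV must have columns {sorted(need)}")
        wide = df.pivot_table(index="label", columns="taxon", values="proportion", fill_value=0.0)
        return cls(
            labels=[str(x) for x in wide.index],
            taxon_ids=[str(x) for x in wide.columns],
            values=wide.to_numpy(),
            harmonization=dict(harmonization or {}),
        )

    def to_csv(self, path: str | Path) -> Path:
        rows = [
            {"label": lab, "taxon": t, "proportion": v}
            for lab, row in zip(self.labels, self.values)
            for t, v in zip(self.taxon_ids, row)
            if v > 0
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)


def harmonize_taxa(comp: CompositionMatrix, centroids: ReferenceCentroids) -> CompositionMatrix:
    """Map artifact taxa onto the centroid taxonomy, pooling within groups.

    Taxa without a harmonization entry that also do not match a centroid taxon
    exactly are pooled into ``"Other"`` (logged).  Mass is conserved exactly;
    output columns are the centroid taxa (plus ``Other`` when used).
    """
    hmap = centroids.harmonization
    target_taxa = list(centroids.taxon_ids)
    cols: dict[str, int] = {t: i for i, t in enumerate(target_taxa)}
    unmapped = []
    dest = []
    for t in comp.taxon_ids:
        if t in hmap:
            g = hmap[t]
        elif t in cols:
            g = t
        else:
            unmapped.append(t)
            g = "Other"
        dest.append(g)
    if unmapped:
        logger.warning("taxa pooled into 'Other': %s", unmapped)
    out_taxa = list(target_taxa)
    if "Other" in dest and "Other" not in cols:
        cols["Other"] = len(out_taxa)
        out_taxa.append("Other")
    for g in dest:
        if g not in cols:
            cols[g] = len(out_taxa)
            out_taxa.append(g)
    values = np.zeros((comp.n_rows, len(out_taxa)))
    for j, g in enumerate(dest):
        values[:, cols[g]] += comp.values[:, j]
    return CompositionMatrix(list(comp.row_ids), out_taxa, values)


def _family(label: str) -> str:
    """Collapse a sub-CST label to its CST family.

    Sub-level letters of the Lactobacillus CSTs collapse (I-A/I-B → I,
    III-A/III-B → III); the diverse CST IV keeps its sub-family letter but
    drops numeric sub-levels (IV-C0…IV-C4 → IV-C).
    """
    lab = label.strip()
    m = re.fullmatch(r"(IV)-([A-Z])\d*", lab)
    if m:
        return f"{m.group(1)}-{m.group(2)}"
    m = re.fullmatch(r"([IVX]+)-[A-Z]\d*", lab)
    if m:
        return m.group(1)
    return lab


def label_topics(
    beta: CompositionMatrix, centroids: ReferenceCentroids
) -> tuple[dict[str, str], pd.DataFrame]:
    """Label each topic by its nearest centroid's CST family.

    Returns the topic → label map and the full topics × centroids Bray–Curtis
    dissimilarity matrix.  When several topics share a family, suffixes
    ``.a``, ``.b``, … are appended in decreasing topic mass order (mass =
    mean of the β row over taxa is not meaningful, so mass here is the order
    of the input rows unless ``beta`` carries a ``mass`` attribute; callers
    with fitted models should pass rows ordered or use ``label_topics_fit``).
    """
    if not centroids.labels:
        raise DataError("empty centroid set")
    harm = harmonize_taxa(beta, centroids)
    cvals = np.zeros((len(centroids.labels), len(harm.taxon_ids)))
    cidx = {t: i for i, t in enumerate(harm.taxon_ids)}
    for i, row in enumerate(centroids.values):
        for t, v in zip(centroids.taxon_ids, row):
            cvals[i, cidx[t]] = v
    D = np.array([[bray_curtis(p, c) for c in cvals] for p in harm.values])
    dissim = pd.DataFrame(D, index=harm.row_ids, columns=centroids.labels)
    nearest = [centroids.labels[int(np.argmin(row))] for row in D]
    families = [_family(lab) for lab in nearest]
    labels: dict[str, str] = {}
    mass = getattr(beta, "topic_mass", None)
    order_key = {rid: (-mass[i] if mass is not None else i) for i, rid in enumerate(harm.row_ids)}
    for fam in sorted(set(families)):
        members = [rid for rid, f in zip(harm.row_ids, families) if f == fam]
        if len(members) == 1:
            labels[members[0]] = fam
        else:
            members = sorted(members, key=lambda r: order_key[r])
            for suffix, rid in zip("abcdefghij", members):
                labels[rid] = f"{fam}.{suffix}"
    return labels, dissim


def label_topics_fit(fit, centroids: ReferenceCentroids) -> tuple[dict[str, str], pd.DataFrame]:
    """``label_topics`` for a TopicModelFit, using mean γ as topic mass."""
    comp = CompositionMatrix(list(fit.topic_ids), list(fit.taxon_ids), fit.beta)
    comp.topic_mass = fit.topic_mass  # decreasing-mass suffix order
    return label_topics(comp, centroids)


def assign_subcst(samples: CompositionMatrix, centroids: ReferenceCentroids) -> list[str]:
    """Assign each sample to the centroid maximizing Yue–Clayton θ (ties → centroid order)."""
    harm = harmonize_taxa(samples, centroids)
    cvals = np.zeros((len(centroids.labels), len(harm.taxon_ids)))
    cidx = {t: i for i, t in enumerate(harm.taxon_ids)}
    for i, row in enumerate(centroids.values):
        for t, v in zip(centroids.taxon_ids, row):
            cvals[i, cidx[t]] = v
    out = []
    for p in harm.values:
        theta = [yue_clayton(p, c) for c in cvals]
        out.append(centroids.labels[int(np.argmax(theta))])
    return out
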
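"""Alignment of topics across models of increasing resolution.

Models fitted at K = K_1 < K_2 < … are connected by weight matrices between
adjacent resolutions; topics are organized into paths, and each topic receives
a coherence score (how consistently it persists along its path) and a
refinement score (how exclusively its mass flows into its children).  The mean
coherence across topics of a model is used to choose the working resolution.

The default "product" weights are W^(m,m+1)_{k,k'} = (1/N)·Σ_i γ^m_{i,k}
γ^{m+1}_{i,k'}; the optional "transport" weights solve a small optimal
transport problem between topic masses with Jensen–Shannon divergence between
β rows as ground cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DataError
from .lda import TopicModelFit


@dataclass
class AlignmentNode:
    model: int  # index into the list of fits
    topic: int  # topic index within the model
    mass: float  # mean γ over samples
    path: int = -1
    coherence: float = float("nan")
    refinement: float = float("nan")


@dataclass
class AlignmentGraph:
    K_values: list[int]
    nodes: list[AlignmentNode]
    weights: list[np.ndarray]  # weights[m]: (K_m, K_{m+1}); entries sum to 1
    gammas: list[np.ndarray] | None = None  # per-model γ (product method only)

    def node(self, model: int, topic: int) -> AlignmentNode:
        return self._index[(model, topic)]

    def __post_init__(self) -> None:
        self._index = {(n.model, n.topic): n for n in self.nodes}

    @property
    def n_models(self) -> int:
        return len(self.K_values)

    def mean_coherence(self, model: int) -> float:
        return float(np.mean([n.coherence for n in self.nodes if n.model == model]))

    def paths(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {}
        for n in self.nodes:
            out.setdefault(n.path, []).append((n.model, n.topic))
        return out

    def to_dict(self) -> dict:
        return {
            "K_values": self.K_values,
            "nodes": [
                {
                    "model": n.model,
                    "topic": n.topic,
                    "mass": n.mass,
                    "path": n.path,
                    "coherence": None if np.isnan(n.coherence) else n.coherence,
                    "refinement": None if np.isnan(n.refinement) else n.refinement,
                }
                for n in self.nodes
            ],
            "weights": [w.tolist() for w in self.weights],
        }


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log(a[nz] / b[nz])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _transport_plan(mass_a: np.ndarray, mass_b: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Exact optimal transport plan via linear programming (small instances)."""
    from scipy.optimize import linprog

    ka, kb = cost.shape
    A_eq = []
    b_eq = []
    for i in range(ka):
        row = np.zeros(ka * kb)
        row[i * kb : (i + 1) * kb] = 1
        A_eq.append(row)
        b_eq.append(mass_a[i])
    for j in range(kb):
        row = np.zeros(ka * kb)
        row[j::kb] = 1
        A_eq.append(row)
        b_eq.append(mass_b[j])
    res = linprog(cost.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return res.x.reshape(ka, kb)


def align_topics(fits: list[TopicModelFit], method: str = "product") -> AlignmentGraph:
    """Build the alignment graph over ≥2 fits sharing the same samples."""
    if len(fits) < 2:
        raise DataError("alignment requires at least two fits")
    sample_sets = {tuple(f.sample_ids) for f in fits}
    if len(sample_sets) != 1:
        raise DataError("all fits must be on the same samples, in the same order")
    fits = sorted(fits, key=lambda f: f.K)
    N = fits[0].gamma.shape[0]
    weights = []
    for fa, fb in zip(fits[:-1], fits[1:]):
        if method == "product":
            W = fa.gamma.T @ fb.gamma / N
        elif method == "transport":
            mass_a = fa.gamma.mean(0)
            mass_b = fb.gamma.mean(0)
            mass_a = mass_a / mass_a.sum()
            mass_b = mass_b / mass_b.sum()
            cost = np.array([[_jsd(pa, pb) for pb in fb.beta] for pa in fa.beta])
            W = _transport_plan(mass_a, mass_b, cost)
            W = W / W.sum()
        else:
            raise DataError(f"unknown alignment method {method!r}")
        weights.append(W)
    nodes = [
        AlignmentNode(model=m, topic=k, mass=float(f.gamma[:, k].mean()))
        for m, f in enumerate(fits)
        for k in range(f.K)
    ]
    graph = AlignmentGraph(
        K_values=[f.K for f in fits],
        nodes=nodes,
        weights=weights,
        gammas=[f.gamma for f in fits] if method == "product" else None,
    )
    _assign_paths(graph)
    return graph


def _outnorm(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=1, keepdims=True)
    return np.divide(W, s, out=np.zeros_like(W), where=s > 0)


def _innorm(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=0, keepdims=True)
    return np.divide(W, s, out=np.zeros_like(W), where=s > 0)


def _assign_paths(graph: AlignmentGraph) -> None:
    """Greedy left-to-right path construction.

    Each topic of model m+1 attaches to the path of its strongest incoming
    normalized weight; among children of one parent, the strongest continuation
    keeps the path id and the rest spawn new ids.  Ties break toward larger
    node mass, then lower topic index.
    """
    next_path = 0
    for k in range(graph.K_values[0]):
        graph.node(0, k).path = next_path
        next_path += 1
    for m, W in enumerate(graph.weights):
        innorm = _innorm(W)
        children_of: dict[int, list[int]] = {}
        for kc in range(W.shape[1]):
            col = innorm[:, kc]
            best = np.max(col)
            cand = np.where(col >= best - 1e-15)[0]
            if len(cand) > 1:  # tie-break: larger parent mass, then lower index
                masses = np.array([graph.node(m, int(k)).mass for k in cand])
                cand = cand[masses >= masses.max() - 1e-15]
            parent = int(cand[0])
            children_of.setdefault(parent, []).append(kc)
        for parent, kids in children_of.items():
            ord_kids = sorted(kids, key=lambda kc: (-W[parent, kc], kc))
            graph.node(m + 1, ord_kids[0]).path = graph.node(m, parent).path
            for kc in ord_kids[1:]:
                graph.node(m + 1, kc).path = next_path
                next_path += 1


def topic_diagnostics(graph: AlignmentGraph) -> AlignmentGraph:
    """Compute per-node coherence and refinement scores (in place; returns graph).

    coherence(v) = mean over the other models containing v's path of
    min(out-normalized, in-normalized) cross-model weight between v and the
    same-path node there.  For the product method the cross-model weight is
    computed directly from the two models' γ matrices, W^(m,m') = γ_mᵀγ_m'/N
    (normalized weights between identical topics are then independent of how
    many resolutions separate the models); for the transport method it is the
    matrix product of the row- (resp. column-) normalized adjacent plans.
    Topics whose path exists in no other model score 0.

    refinement(u) = Σ_children outnorm(u→v)·innorm(u←v); undefined (NaN) for
    the last model.
    """
    if not graph.weights:
        raise DataError("graph has no edges")
    M = graph.n_models
    outn = [_outnorm(W) for W in graph.weights]
    inn = [_innorm(W) for W in graph.weights]
    cross_out: dict[tuple[int, int], np.ndarray] = {}
    cross_in: dict[tuple[int, int], np.ndarray] = {}
    if graph.gammas is not None:
        N = graph.gammas[0].shape[0]
        for a in range(M - 1):
            for b in range(a + 1, M):
                W = graph.gammas[a].T @ graph.gammas[b] / N
                cross_out[(a, b)] = _outnorm(W)
                cross_in[(a, b)] = _innorm(W)
    else:  # compose row-/column-normalized adjacent weights
        for a in range(M - 1):
            cross_out[(a, a + 1)] = outn[a]
            cross_in[(a, a + 1)] = inn[a]
            for b in range(a + 2, M):
                cross_out[(a, b)] = cross_out[(a, b - 1)] @ outn[b - 1]
                cross_in[(a, b)] = cross_in[(a, b - 1)] @ inn[b - 1]
    path_node: dict[tuple[int, int], int] = {}
    for n in graph.nodes:
        path_node[(n.path, n.model)] = n.topic
    for n in graph.nodes:
        vals = []
        for m2 in range(M):
            if m2 == n.model:
                continue
            k2 = path_node.get((n.path, m2))
            if k2 is None:
                continue
            a, b = sorted((n.model, m2))
            ka = n.topic if n.model == a else k2
            kb = k2 if n.model == a else n.topic
            vals.append(min(cross_out[(a, b)][ka, kb], cross_in[(a, b)][ka, kb]))
        n.coherence = float(np.clip(np.mean(vals), 0.0, 1.0)) if vals else 0.0
        if n.model < M - 1:
            n.refinement = float(
                np.clip(np.sum(outn[n.model][n.topic] * inn[n.model][n.topic]), 0.0, 1.0)
            )
    return graph


def select_k(graph: AlignmentGraph, criterion: str = "coherence") -> int:
    """Working resolution: the K whose model maximizes mean topic coherence (ties → smaller K)."""
    if criterion != "coherence":
        raise DataError(f"unknown criterion {criterion!r}")
    if any(np.isnan(n.coherence) for n in graph.nodes):
        topic_diagnostics(graph)
    means = [graph.mean_coherence(m) for m in range(graph.n_models)]
    best = max(range(len(means)), key=lambda m: (means[m], -graph.K_values[m]))
    return graph.K_values[best]
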
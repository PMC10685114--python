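"""Latent Dirichlet allocation on taxon count tables.

Samples (documents) are modelled as mixtures of K topics; each topic is a
distribution over taxa.  Counts enter the likelihood directly — no prior
normalization — so library size is part of the model.

Inference is a blocked Gibbs sampler on the augmented model: given (θ, β) the
latent topic allocation of each (sample, taxon) count cell is multinomial, and
given the allocations θ and β have conjugate Dirichlet full conditionals.  The
sweep cost scales with the number of nonzero cells rather than with the number
of sequenced reads, which keeps full-length chains tractable at realistic
library sizes (10⁴–10⁵ reads/sample).  Point estimates of β and γ are posterior
means of the smoothed allocation counts over thinned post-burn-in sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .data_model import CountMatrix, DataError


@dataclass
class TopicModelFit:
    """A fitted LDA model.

    beta : (K, V) row-stochastic topic-taxon matrix (β_{k,j}).
    gamma : (N, K) row-stochastic sample-topic matrix (γ_{i,k}).
    """

    K: int
    beta: np.ndarray
    gamma: np.ndarray
    alpha: float
    eta: float
    seed: int
    n_iterations: int
    burn_in: int
    log_likelihood: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    topic_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.topic_ids:
            self.topic_ids = [f"T{k + 1}" for k in range(self.K)]
        assert self.beta.shape == (self.K, len(self.taxon_ids))
        assert self.gamma.shape == (len(self.sample_ids), self.K)
        if not np.allclose(self.beta.sum(1), 1.0, atol=1e-8):
            raise DataError("beta rows must sum to 1")
        if not np.allclose(self.gamma.sum(1), 1.0, atol=1e-8):
            raise DataError("gamma rows must sum to 1")

    @property
    def topic_mass(self) -> np.ndarray:
        """Mean γ over samples — the overall prevalence of each topic."""
        return self.gamma.mean(axis=0)

    def save(self, outdir: str | Path) -> Path:
        """Serialize as a directory of TSV matrices plus a JSON manifest."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.beta, index=self.topic_ids, columns=self.taxon_ids).to_csv(
            outdir / "beta.tsv", sep="\t"
        )
        pd.DataFrame(self.gamma, index=self.sample_ids, columns=self.topic_ids).to_csv(
            outdir / "gamma.tsv", sep="\t"
        )
        manifest = {
            "K": self.K,
            "alpha": self.alpha,
            "eta": self.eta,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "log_likelihood": [float(x) for x in self.log_likelihood],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return outdir


def _em_sweeps(
    X: np.ndarray,
    alpha: float,
    eta: float,
    theta: np.ndarray,
    beta: np.ndarray,
    nz_cols: list[int],
    n_iter: int,
    temperature: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    N, K = theta.shape
    V = beta.shape[1]
    for _ in range(n_iter):
        ndk = np.full((N, K), alpha)
        nkw = np.full((K, V), eta)
        for w in nz_cols:
            r = theta * beta[:, w]
            if temperature != 1.0:
                r = r ** (1.0 / temperature)
            r /= r.sum(1, keepdims=True)
            contrib = X[:, w, None] * r
            ndk += contrib
            nkw[:, w] += contrib.sum(axis=0)
        theta = ndk / ndk.sum(1, keepdims=True)
        beta = nkw / nkw.sum(1, keepdims=True)
    return theta, beta


def _em_start(
    X: np.ndarray,
    K: int,
    alpha: float,
    eta: float,
    rng: np.random.Generator,
    nz_cols: list[int],
    n_restarts: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Annealed EM for (θ, β); best log-likelihood over seeded restarts.

    Plain EM on these likelihood surfaces is easily trapped in modes that
    misallocate rare taxa; tempering the responsibilities (T = 2 → 1) before
    the final T = 1 polish reliably reaches the dominant basin.  The polish
    stops early once the log-likelihood plateaus.
    """
    N, V = X.shape
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        g = rng.standard_gamma(1.0, size=(N, K))
        theta = g / g.sum(1, keepdims=True)
        g = rng.standard_gamma(1.0, size=(K, V))
        beta = g / g.sum(1, keepdims=True)
        for T in (2.0, 1.5, 1.2):
            theta, beta = _em_sweeps(X, alpha, eta, theta, beta, nz_cols, 60, T)
        ll_prev = -np.inf
        for _ in range(6):  # up to 300 polish sweeps, stop on plateau
            theta, beta = _em_sweeps(X, alpha, eta, theta, beta, nz_cols, 50)
            ll = _loglik(X, theta, beta)
            if ll - ll_prev < 0.1:
                break
            ll_prev = ll
        ll = _loglik(X, theta, beta)
        if best is None or ll > best[0]:
            best = (ll, theta, beta)
    return best[1], best[2]


def _loglik(counts: np.ndarray, theta: np.ndarray, beta: np.ndarray) -> float:
    mix = theta @ beta
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log(mix[nz] + 1e-300)))


def fit_lda(
    cm: CountMatrix,
    K: int,
    alpha: float | None = None,
    eta: float = 0.01,
    seed: int = 0,
    n_iterations: int = 2000,
    burn_in: int = 500,
    thin: int = 10,
) -> TopicModelFit:
    """Fit a K-topic LDA model by blocked Gibbs sampling.

    Defaults: alpha = 1/K, eta = 0.01, 2000 sweeps with 500 burn-in,
    posterior means over every 10th post-burn-in sweep.  Deterministic under
    ``seed``.  Taxa are processed in a canonical content-sorted order so that
    permuting input taxon columns permutes the fitted β columns identically.
    """
    if K < 1:
        raise DataError("K must be ≥ 1")
    if K > cm.n_taxa:
        raise DataError(f"K={K} exceeds the number of taxa ({cm.n_taxa})")
    if n_iterations <= burn_in:
        raise DataError("n_iterations must exceed burn_in")
    if (cm.library_sizes == 0).any():
        zero = [s for s, l in zip(cm.sample_ids, cm.library_sizes) if l == 0]
        raise DataError(f"zero-count samples: {zero}")
    if alpha is None:
        alpha = 1.0 / K

    counts = cm.counts.astype(np.int64)
    N, V = counts.shape
    # Canonical taxon order: sort columns by content so the sampler's RNG
    # consumption is independent of the input column order.
    order = np.lexsort(counts[::-1])
    inv = np.empty(V, dtype=int)
    inv[order] = np.arange(V)
    X = counts[:, order]

    rng = np.random.default_rng(seed)
    nz_cols_init = [w for w in range(V) if X[:, w].any()]
    # EM warm start (best of a few restarts) — the blocked sampler mixes
    # slowly between modes when memberships are near-deterministic, so the
    # chain is started at a high-probability mode found deterministically
    theta, beta = _em_start(X, K, alpha, eta, rng, nz_cols_init)

    beta_acc = np.zeros((K, V))
    gamma_acc = np.zeros((N, K))
    n_acc = 0
    ll_trace = np.empty(n_iterations)
    nz_cols = [w for w in range(V) if X[:, w].any()]

    for it in range(n_iterations):
        ndk = np.zeros((N, K))
        nkw = np.zeros((K, V))
        for w in nz_cols:
            p = theta * beta[:, w]  # (N, K)
            p /= p.sum(1, keepdims=True)
            z = rng.multinomial(X[:, w], p)  # (N, K)
            ndk += z
            nkw[:, w] = z.sum(axis=0)
        g = rng.standard_gamma(alpha + ndk)
        theta = g / g.sum(1, keepdims=True)
        g = rng.standard_gamma(eta + nkw)
        beta = g / g.sum(1, keepdims=True)
        ll_trace[it] = _loglik(X, theta, beta)
        if it >= burn_in and (it - burn_in) % thin == 0:
            # smoothed posterior-mean point estimates from allocation counts
            b = nkw + eta
            beta_acc += b / b.sum(1, keepdims=True)
            gm = ndk + alpha
            gamma_acc += gm / gm.sum(1, keepdims=True)
            n_acc += 1

    beta_hat = (beta_acc / n_acc)[:, inv]
    beta_hat /= beta_hat.sum(1, keepdims=True)
    gamma_hat = gamma_acc / n_acc
    gamma_hat /= gamma_hat.sum(1, keepdims=True)
    return TopicModelFit(
        K=K,
        beta=beta_hat,
        gamma=gamma_hat,
        alpha=alpha,
        eta=eta,
        seed=seed,
        n_iterations=n_iterations,
        burn_in=burn_in,
        log_likelihood=ll_trace,
        sample_ids=list(cm.sample_ids),
        taxon_ids=list(cm.taxon_ids),
    )


def fit_lda_range(
    cm: CountMatrix,
    K_values: list[int],
    alpha: float | None = None,
    eta: float = 0.01,
    seed: int = 0,
    n_iterations: int = 2000,
    burn_in: int = 500,
    thin: int = 10,
) -> list[TopicModelFit]:
    """Independent fits for an increasing list of K; per-K seeds derived from the base seed."""
    if list(K_values) != sorted(set(K_values)):
        raise DataError("K_values must be strictly increasing")
    fits = []
    for K in K_values:
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(K,)).generate_state(1)[0] % (2**31))
        fits.append(
            fit_lda(
                cm, K, alpha=alpha, eta=eta, seed=sub_seed,
                n_iterations=n_iterations, burn_in=burn_in, thin=thin,
            )
        )
    return fits


def perplexity(fit: TopicModelFit, cm: CountMatrix, n_em: int = 50) -> float:
    """Held-out per-token perplexity under the fitted β.

    Document mixtures for the held-out samples are re-estimated by folding-in
    (multiplicative EM updates of θ with β fixed), then perplexity =
    exp(−log-likelihood / total tokens).
    """
    if cm.taxon_ids != fit.taxon_ids:
        raise DataError("held-out table must share the fit's taxa")
    X = cm.counts.astype(float)
    N = X.shape[0]
    theta = np.full((N, fit.K), 1.0 / fit.K)
    beta = fit.beta + 1e-12
    beta = beta / beta.sum(1, keepdims=True)
    for _ in range(n_em):
        mix = theta @ beta + 1e-300
        theta = theta * ((X / mix) @ beta.T)
        theta += fit.alpha * 1e-3
        theta /= theta.sum(1, keepdims=True)
    ll = _loglik(X, theta, beta)
    return float(np.exp(-ll / X.sum()))
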
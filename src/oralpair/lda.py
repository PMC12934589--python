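"""LDA topic modeling of scaled relative abundances.

Microbiome samples become "documents" whose "tokens" are taxa observations:
TSS relative abundances are multiplied by a scaling factor S and rounded to
integers, so every sample carries ~S tokens regardless of sequencing depth.
A collapsed Gibbs sampler fits K latent topics; the topic-taxon matrix
(beta) and sample-topic matrix (gamma) are posterior-mean estimates from the
final sampler state:

    beta[k, w]  = (n_kw + eta)  / (n_k + V * eta)
    gamma[d, k] = (n_dk + alpha) / (n_d + K * alpha)

Model selection uses four curves over a K grid — Griffiths2004 (harmonic-mean
estimate of the log marginal likelihood; maximise), CaoJuan2009 (mean
pairwise cosine similarity of topics; minimise), Arun2010 (symmetric KL
between the normalised singular values of beta and the document-length-
weighted topic proportions; minimise) and Deveaud2014 (mean pairwise
half-symmetric KL between topics; maximise) — combined into one deterministic
choice by min-max normalising each curve over the grid and minimising
(cao + arun - deveaud - griffiths).

Topic/specimen-type association applies the paired signed-rank test to
per-patient gamma differences with BH correction across topics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import _gibbs
from .ordination import DistanceMatrix, silhouette_by_group
from .tables import CountTable, SampleMetadata, paired_arrays
from .transforms import bh_fdr, tss, wilcoxon_signed_rank


@dataclasses.dataclass
class ScaledCorpus:
    matrix: np.ndarray  # docs x vocab, integer token counts
    docs: list[str]
    vocab: list[str]
    scale: int


@dataclasses.dataclass
class LdaModel:
    K: int
    alpha: float
    eta: float
    beta: np.ndarray  # K x V, rows sum to 1
    gamma: np.ndarray  # D x K, rows sum to 1
    loglik_trace: np.ndarray
    seed: int
    iterations: int
    burn_in: int
    thin: int
    docs: list[str]
    vocab: list[str]

    def to_json(self, path: Path) -> None:
        payload = {
            "K": self.K,
            "alpha": self.alpha,
            "eta": self.eta,
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "loglik_trace": self.loglik_trace.tolist(),
            "seed": self.seed,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "docs": self.docs,
            "vocab": self.vocab,
        }
        Path(path).write_text(json.dumps(payload))


def build_scaled_corpus(ct: CountTable, S: int = 1000) -> ScaledCorpus:
    """Round(TSS x S), half away from zero; documents are samples."""
    if S < 10:
        raise ValueError("scaling factor S must be >= 10")
    rel = tss(ct).values  # taxa x samples
    scaled = np.floor(rel * S + 0.5).astype(np.int64)  # values are >= 0
    matrix = scaled.T  # docs x vocab
    totals = matrix.sum(axis=1)
    if np.any(totals == 0):
        bad = ct.samples[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero tokens at S={S}")
    return ScaledCorpus(matrix, list(ct.samples), list(ct.taxa), int(S))


def _expand_tokens(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    docs, words = np.nonzero(matrix)
    reps = matrix[docs, words]
    return (
        np.repeat(docs, reps).astype(np.int32),
        np.repeat(words, reps).astype(np.int32),
    )


def _complete_loglik(n_kw: np.ndarray, n_dk: np.ndarray, alpha: float, eta: float) -> float:
    """log P(w, z | alpha, eta) of the collapsed state."""
    K, V = n_kw.shape
    D = n_dk.shape[0]
    n_k = n_kw.sum(axis=1)
    n_d = n_dk.sum(axis=1)
    lw = (
        K * gammaln(V * eta)
        - K * V * gammaln(eta)
        + gammaln(n_kw + eta).sum()
        - gammaln(n_k + V * eta).sum()
    )
    lz = (
        D * gammaln(K * alpha)
        - D * K * gammaln(alpha)
        + gammaln(n_dk + alpha).sum()
        - gammaln(n_d + K * alpha).sum()
    )
    return float(lw + lz)


def fit_lda_gibbs(
    corpus: ScaledCorpus,
    K: int,
    alpha: float | None = None,
    eta: float = 0.1,
    iterations: int = 2000,
    burn_in: int = 1000,
    thin: int = 50,
    seed: int = 0,
) -> LdaModel:
    """Collapsed Gibbs LDA; exactly reproducible given (corpus, K, params, seed)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    total_tokens = int(corpus.matrix.sum())
    if K > total_tokens:
        raise ValueError(f"K={K} exceeds the {total_tokens} tokens in the corpus")
    if alpha is None:
        alpha = 50.0 / K
    D, V = corpus.matrix.shape
    doc_ids, word_ids = _expand_tokens(corpus.matrix)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    _gibbs.seed_rng(int(seed) & 0x7FFFFFFF)
    z = _gibbs.init_assignments(doc_ids, word_ids, K, n_dk, n_kw, n_k)
    _gibbs.sweep(doc_ids, word_ids, z, n_dk, n_kw, n_k, float(alpha), float(eta), int(burn_in))
    trace = []
    done = burn_in
    while done < iterations:
        step = min(thin, iterations - done)
        _gibbs.sweep(doc_ids, word_ids, z, n_dk, n_kw, n_k, float(alpha), float(eta), int(step))
        done += step
        trace.append(_complete_loglik(n_kw, n_dk, alpha, eta))
    beta = (n_kw + eta) / (n_kw.sum(axis=1, keepdims=True) + V * eta)
    gamma = (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + K * alpha)
    return LdaModel(
        K=K,
        alpha=float(alpha),
        eta=float(eta),
        beta=beta,
        gamma=gamma,
        loglik_trace=np.array(trace),
        seed=int(seed),
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        docs=list(corpus.docs),
        vocab=list(corpus.vocab),
    )


# ---------------------------------------------------------------- K selection

def griffiths2004(loglik_trace: np.ndarray) -> float:
    """Harmonic-mean estimate of log P(w | K) from the post-burn-in trace."""
    ll = np.asarray(loglik_trace, dtype=float)
    return float(-(logsumexp(-ll) - np.log(len(ll))))


def caojuan2009(beta: np.ndarray) -> float:
    """Mean pairwise cosine similarity between topic-taxon rows."""
    norms = np.linalg.norm(beta, axis=1, keepdims=True)
    unit = beta / norms
    sim = unit @ unit.T
    K = beta.shape[0]
    iu = np.triu_indices(K, k=1)
    return float(sim[iu].mean())


def arun2010(beta: np.ndarray, gamma: np.ndarray, doc_lengths: np.ndarray) -> float:
    """Symmetric KL between singular-value and topic-proportion spectra."""
    sv = np.linalg.svd(beta, compute_uv=False)
    c1 = sv / sv.sum()
    weighted = doc_lengths @ gamma
    c2 = weighted / weighted.sum()
    c1 = np.maximum(np.sort(c1)[::-1], 1e-12)
    c2 = np.maximum(np.sort(c2)[::-1], 1e-12)
    return float(np.sum(c1 * np.log(c1 / c2)) + np.sum(c2 * np.log(c2 / c1)))


def deveaud2014(beta: np.ndarray) -> float:
    """Mean over topic pairs of half the symmetric KL divergence."""
    K = beta.shape[0]
    b = np.maximum(beta, 1e-12)
    total = 0.0
    n = 0
    for j in range(K):
        for k in range(j + 1, K):
            kl_jk = np.sum(b[j] * np.log(b[j] / b[k]))
            kl_kj = np.sum(b[k] * np.log(b[k] / b[j]))
            total += 0.5 * (kl_jk + kl_kj)
            n += 1
    return float(total / n)


@dataclasses.dataclass
class KSelectionCurve:
    k_grid: list[int]
    metrics: pd.DataFrame  # index K, columns griffiths2004/caojuan2009/arun2010/deveaud2014
    chosen_k: int
    degenerate: bool = False


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def k_selection(
    corpus: ScaledCorpus,
    k_grid: Sequence[int],
    seed: int = 0,
    **fit_kwargs,
) -> KSelectionCurve:
    """Fit the grid (same seed per K) and choose K by the joint-normalised rule."""
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if min(k_grid) < 2:
        raise ValueError("k_grid must contain only K >= 2 (pairwise metrics undefined at K=1)")
    doc_lengths = corpus.matrix.sum(axis=1).astype(float)
    rows = {}
    for K in k_grid:
        model = fit_lda_gibbs(corpus, K, seed=seed, **fit_kwargs)
        rows[K] = {
            "griffiths2004": griffiths2004(model.loglik_trace),
            "caojuan2009": caojuan2009(model.beta),
            "arun2010": arun2010(model.beta, model.gamma, doc_lengths),
            "deveaud2014": deveaud2014(model.beta),
        }
    metrics = pd.DataFrame.from_dict(rows, orient="index").loc[k_grid]
    if len(k_grid) == 1:
        return KSelectionCurve(k_grid, metrics, k_grid[0], degenerate=True)
    score = (
        _minmax(metrics["caojuan2009"].to_numpy())
        + _minmax(metrics["arun2010"].to_numpy())
        - _minmax(metrics["deveaud2014"].to_numpy())
        - _minmax(metrics["griffiths2004"].to_numpy())
    )
    chosen = k_grid[int(np.argmin(score))]  # argmin takes the smallest K on ties
    return KSelectionCurve(k_grid, metrics, chosen)


# ------------------------------------------------------- scaling factor choice

def select_scaling_factor(
    ct: CountTable,
    md: SampleMetadata,
    K: int,
    s_grid: Sequence[int] = (10, 100, 1000, 10000),
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose S maximising the sum of per-type median silhouettes on gamma."""
    groups = md.frame["specimen_type"].to_dict()
    rows = []
    for S in s_grid:
        row: dict = {"S": int(S)}
        try:
            corpus = build_scaled_corpus(ct, S)
        except ValueError as exc:
            row.update({"skipped": str(exc)})
            rows.append(row)
            continue
        model = fit_lda_gibbs(corpus, K, seed=seed, **fit_kwargs)
        d = _euclidean_dm(model.gamma, model.docs)
        sil = silhouette_by_group(d, groups)
        row.update(
            {
                "silhouette_plaque": sil.get("plaque", np.nan),
                "silhouette_abscess": sil.get("abscess", np.nan),
                "score": sil.get("plaque", 0.0) + sil.get("abscess", 0.0),
                "skipped": "",
            }
        )
        rows.append(row)
    diag = pd.DataFrame(rows)
    ok = diag[diag["skipped"] == ""]
    if ok.empty:
        raise ValueError("every scaling factor was skipped")
    best = ok.loc[ok["score"].idxmax(), "S"]
    return int(best), diag


def _euclidean_dm(points: np.ndarray, ids: list[str]) -> DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(list(ids), squareform(pdist(points, "euclidean")), "euclidean")


# ------------------------------------------------- topic/type association etc.

def topic_type_association(model: LdaModel, md: SampleMetadata) -> pd.DataFrame:
    """Paired signed-rank test of per-patient gamma differences per topic."""
    dummy = CountTable(
        [f"k{k}" for k in range(model.K)], list(model.docs),
        np.zeros((model.K, len(model.docs)), dtype=int),
    )
    _, g_plaque, g_abscess = paired_arrays(dummy, md.subset(model.docs), model.gamma.T)
    p = np.array([wilcoxon_signed_rank(g_plaque[k] - g_abscess[k]).p_value for k in range(model.K)])
    q = bh_fdr(p)
    med_p = np.median(g_plaque, axis=1)
    med_a = np.median(g_abscess, axis=1)
    classes = []
    for k in range(model.K):
        if q[k] < 0.05 and med_p[k] > med_a[k]:
            classes.append("plaque")
        elif q[k] < 0.05 and med_a[k] > med_p[k]:
            classes.append("abscess")
        else:
            classes.append("shared")
    return pd.DataFrame(
        {
            "topic": [f"topic_{k+1}" for k in range(model.K)],
            "p": p,
            "q": q,
            "median_gamma_plaque": med_p,
            "median_gamma_abscess": med_a,
            "class": classes,
        }
    ).set_index("topic")


def topic_drivers(model: LdaModel, top_n: int = 10) -> dict[str, pd.DataFrame]:
    """Per topic, the top_n taxa by beta score (ties broken by taxon name)."""
    out = {}
    vocab = np.array(model.vocab)
    for k in range(model.K):
        row = model.beta[k]
        order = np.lexsort((vocab, -row))[:top_n]
        out[f"topic_{k+1}"] = pd.DataFrame(
            {"taxon": vocab[order], "beta": row[order]}
        ).set_index("taxon")
    return out


def embed_gamma(
    model: LdaModel, md: SampleMetadata, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Seeded 2-D UMAP embedding of gamma rows + per-type median silhouettes."""
    n = model.gamma.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to embed")
    import umap  # deferred: slow import

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=int(seed) & 0x7FFFFFFF,
    )
    coords = reducer.fit_transform(model.gamma)
    emb = pd.DataFrame(coords, index=model.docs, columns=["umap1", "umap2"])
    d = _euclidean_dm(coords, model.docs)
    groups = md.frame["specimen_type"].to_dict()
    sil = silhouette_by_group(d, groups)
    return emb, sil
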
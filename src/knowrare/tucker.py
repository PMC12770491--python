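"""TuckER knowledge-graph embedding and cosine-similarity source selection.

A triple (v_i, r_k, v_j) is scored by the trilinear form

    T_ikj = W ×1 E_{v_i} ×2 R_{r_k} ×3 E_{v_j}
          = sum_{abc} W[a,b,c] E_i[a] R_k[b] E_j[c],

with entity embeddings E, relation embeddings R and a shared core tensor
W in R^{d x d x d}. Training minimises a sigmoid binary cross-entropy
link-prediction objective: observed triples are positives (optionally
weighted by their graph edge weight), corrupted-tail draws are negatives.
Gradients of the trilinear form are computed in closed form (einsum) and fed
to Adam.

Source-domain selection for a target condition picks the k candidates with
the highest cosine similarity to the target's entity embedding. Because the
subset objective is a sum of per-member cosines, the arg-max subset of size k
equals the top-k by individual score; ties at rank k break lexicographically
by condition code for determinism.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kg import ConditionGraph, RELATIONS
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TripleSet",
    "TuckerParams",
    "DomainSelection",
    "triples_from_graph",
    "tucker_score",
    "tucker_scores",
    "train_tucker",
    "embedding_cosine",
    "select_sources",
]


@dataclass
class TripleSet:
    heads: np.ndarray  # int indices
    relations: np.ndarray
    tails: np.ndarray
    weights: np.ndarray
    entities: list[str]
    relation_names: list[str]

    def __len__(self) -> int:
        return len(self.heads)


@dataclass
class TuckerParams:
    E: np.ndarray  # (n_entities, d)
    R: np.ndarray  # (n_relations, d)
    W: np.ndarray  # (d, d, d)
    entities: list[str] = field(default_factory=list)

    def embedding(self, code: str) -> np.ndarray:
        return self.E[self.entities.index(code)]


@dataclass
class DomainSelection:
    target: str
    ranked: list[tuple[str, float]]  # all candidates, score non-increasing
    selected: list[str]  # top-k


def triples_from_graph(graph: ConditionGraph) -> TripleSet:
    """One triple per directed edge (symmetric relations contribute both
    directions), carrying the edge weight."""
    ent = list(graph.nodes)
    ent_idx = {c: i for i, c in enumerate(ent)}
    rel_names = list(RELATIONS)
    rel_idx = {r: i for i, r in enumerate(rel_names)}
    h, r, t, w = [], [], [], []
    for head, tail, rel, weight in graph.directed_edges():
        h.append(ent_idx[head])
        r.append(rel_idx[rel])
        t.append(ent_idx[tail])
        w.append(weight)
    return TripleSet(np.array(h, dtype=int), np.array(r, dtype=int),
                     np.array(t, dtype=int), np.array(w, dtype=float),
                     ent, rel_names)


def tucker_score(e_i: np.ndarray, r_k: np.ndarray, e_j: np.ndarray,
                 W: np.ndarray) -> float:
    """Trilinear score of a single triple."""
    if not (e_i.shape[0] == r_k.shape[0] == e_j.shape[0] == W.shape[0]
            and W.shape[0] == W.shape[1] == W.shape[2]):
        raise ValueError("embedding / core tensor dimension mismatch")
    return float(np.einsum("abc,a,b,c->", W, e_i, r_k, e_j))


def tucker_scores(params: TuckerParams, heads: np.ndarray, rels: np.ndarray,
                  tails: np.ndarray) -> np.ndarray:
    """Vectorised trilinear scores for index arrays."""
    Ei = params.E[heads]
    Rk = params.R[rels]
    Ej = params.E[tails]
    return np.einsum("abc,na,nb,nc->n", params.W, Ei, Rk, Ej)


def train_tucker(triples: TripleSet, dim: int = 16, epochs: int = 1000,
                 learning_rate: float = 1e-2, n_negatives: int = 5,
                 weight_aware: bool = True, seed: int = 0) -> TuckerParams:
    """Fit TuckER by sigmoid-BCE link prediction with corrupted-tail negatives.

    Full-batch updates (desk-scale graphs have at most a few thousand
    triples), so ``epochs`` counts optimisation steps; the defaults are sized
    for graphs of tens of nodes. Deterministic under a fixed seed. Gradients
    of the trilinear form are closed-form contractions staged through
    (batch, d, d) intermediates to keep the cost at O(n d^3).
    """
    if len(triples) == 0:
        raise ValueError("cannot train on an empty triple set")
    rng = np.random.default_rng(seed)
    n_ent = len(triples.entities)
    n_rel = len(triples.relation_names)
    E = Tensor.param(rng.normal(scale=0.1, size=(n_ent, dim)))
    R = Tensor.param(rng.normal(scale=0.1, size=(n_rel, dim)))
    W = Tensor.param(rng.normal(scale=0.1, size=(dim, dim, dim)))
    opt = Adam([E, R, W], lr=learning_rate)

    n_pos = len(triples)
    pos_w = triples.weights if weight_aware else np.ones(n_pos)

    for _ in range(epochs):
        neg_tails = rng.integers(0, n_ent, size=n_pos * n_negatives)
        heads = np.concatenate([triples.heads, np.repeat(triples.heads, n_negatives)])
        rels = np.concatenate([triples.relations, np.repeat(triples.relations, n_negatives)])
        tails = np.concatenate([triples.tails, neg_tails])
        labels = np.concatenate([np.ones(n_pos), np.zeros(n_pos * n_negatives)])
        # a corrupted tail that lands on the source triple's own tail would be
        # the positive itself relabelled 0; drop those (zero loss weight)
        neg_w = (neg_tails != np.repeat(triples.tails, n_negatives)).astype(float)
        w = np.concatenate([pos_w, neg_w])
        n = len(labels)

        Ei, Rk, Ej = E.data[heads], R.data[rels], E.data[tails]
        WR = np.einsum("nb,abc->nac", Rk, W.data, optimize=True)  # W x2 R_k
        scores = np.einsum("nac,na,nc->n", WR, Ei, Ej, optimize=True)
        p = 1.0 / (1.0 + np.exp(-scores))
        coeff = w * (p - labels) / n  # dL/dscore for weighted mean BCE

        gEi = np.einsum("nac,nc->na", WR, Ej) * coeff[:, None]
        gEj = np.einsum("nac,na->nc", WR, Ei) * coeff[:, None]
        EiW = np.einsum("na,abc->nbc", Ei, W.data, optimize=True)  # W x1 E_i
        gRk = np.einsum("nbc,nc->nb", EiW, Ej) * coeff[:, None]
        kr = (Ei * coeff[:, None])[:, :, None] * Rk[:, None, :]  # (n, a, b)
        gW = (kr.reshape(n, -1).T @ Ej).reshape(W.data.shape)

        gradE = np.zeros_like(E.data)
        np.add.at(gradE, heads, gEi)
        np.add.at(gradE, tails, gEj)
        gradR = np.zeros_like(R.data)
        np.add.at(gradR, rels, gRk)

        opt.zero_grad()
        E.grad, R.grad, W.grad = gradE, gradR, gW
        opt.step()

    return TuckerParams(E.data.copy(), R.data.copy(), W.data.copy(),
                        entities=list(triples.entities))


def embedding_cosine(e_i: np.ndarray, e_j: np.ndarray) -> float:
    ni, nj = np.linalg.norm(e_i), np.linalg.norm(e_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for zero-norm embedding")
    return float(e_i @ e_j / (ni * nj))


def select_sources(params: TuckerParams, target: str,
                   candidates: list[str] | None = None,
                   k: int | None = None) -> DomainSelection:
    """Rank candidates by cosine similarity to the target embedding and keep
    the top k. Default candidate pool: every other condition in the
    vocabulary; default k: ceil(0.10 * #candidates)."""
    if candidates is None:
        candidates = [c for c in params.entities if c != target]
    if target in candidates:
        raise ValueError("target must not appear among candidates")
    if not candidates:
        raise ValueError("no candidate source conditions")
    if k is None:
        k = int(np.ceil(0.10 * len(candidates)))
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(candidates):
        warnings.warn(f"k={k} exceeds the {len(candidates)} candidates; selecting all")
        k = len(candidates)
    e_t = params.embedding(target)
    scored = [(c, embedding_cosine(e_t, params.embedding(c))) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    return DomainSelection(target, scored, [c for c, _ in scored[:k]])
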
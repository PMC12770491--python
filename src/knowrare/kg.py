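"""Heterogeneous condition knowledge graph over level-3 condition codes.

Three typed relations encode clinical similarity between conditions:

* ``r1_diagnosis`` — row-normalised diagnosis co-occurrence frequency,
  w_ij = CoOcc(v_i, v_j) / sum_k CoOcc(v_i, v_k) (directed; row-normalisation
  breaks symmetry);
* ``r2_record`` — inverse-L2 similarity of condition signatures,
  w_ij = 1 / (1 + ||s_i - s_j||_2), where the signature s_v concatenates the
  element-wise mean and standard deviation of the imputed, normalised (T, V)
  grids of the condition's patients; only the top half of pairs is retained;
* ``r3_drug`` — Jaccard similarity of condition drug sets, zero-weight pairs
  dropped, top half retained.

Retention cuts act on unordered candidate pairs before the symmetric
relations are expanded to both directions; ties at the cut weight are all
retained so the result is order-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

R1_DIAGNOSIS = "r1_diagnosis"
R2_RECORD = "r2_record"
R3_DRUG = "r3_drug"
RELATIONS = (R1_DIAGNOSIS, R2_RECORD, R3_DRUG)
SYMMETRIC_RELATIONS = frozenset({R2_RECORD, R3_DRUG})

Edge = tuple[str, str, float]  # (head, tail, weight)

__all__ = [
    "ConditionGraph",
    "cooccurrence_edges",
    "condition_signatures",
    "record_edges",
    "drug_edges",
    "assemble_graph",
    "prune_graph",
    "build_condition_graph",
]


@dataclass
class ConditionGraph:
    """Typed weighted multigraph over condition codes.

    Symmetric relations (r2, r3) store one entry per unordered pair; the
    directed edge view (`directed_edges`) expands them to both directions.
    """

    nodes: list[str]
    edges: dict[str, list[Edge]] = field(default_factory=dict)

    def relation_edges(self, relation: str) -> list[Edge]:
        return self.edges.get(relation, [])

    def directed_edges(self) -> list[tuple[str, str, str, float]]:
        out = []
        for rel in RELATIONS:
            for h, t, w in self.edges.get(rel, []):
                out.append((h, t, rel, w))
                if rel in SYMMETRIC_RELATIONS:
                    out.append((t, h, rel, w))
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for h, t, rel, w in self.directed_edges():
            g.add_edge(h, t, key=rel, relation=rel, weight=w)
        return g

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "edges.tsv", "w") as fh:
            fh.write("head\ttail\trelation\tweight\n")
            for h, t, rel, w in self.directed_edges():
                fh.write(f"{h}\t{t}\t{rel}\t{w!r}\n")
        with open(directory / "graph.json", "w") as fh:
            json.dump({"nodes": self.nodes,
                       "n_edges": {r: len(e) for r, e in self.edges.items()}}, fh, indent=2)


def cooccurrence_edges(records: list[set[str]],
                       universe: set[str] | None = None) -> list[Edge]:
    """Directed r1 edges: normalised co-occurrence frequency over diagnosis records.

    Each record is the set of level-3 codes in one patient's diagnosis list;
    CoOcc counts records containing both codes.
    """
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        codes = sorted(rec if universe is None else rec & universe)
        for a_i, a in enumerate(codes):
            for b in codes[a_i + 1:]:
                counts[(a, b)] = counts.get((a, b), 0) + 1
    totals: dict[str, float] = {}
    for (a, b), c in counts.items():
        totals[a] = totals.get(a, 0) + c
        totals[b] = totals.get(b, 0) + c
    edges: list[Edge] = []
    for (a, b), c in sorted(counts.items()):
        edges.append((a, b, c / totals[a]))
        edges.append((b, a, c / totals[b]))
    return edges


def condition_signatures(tensors_by_condition: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Signature s_v: element-wise mean and std over the condition's (n, T, V)
    grids, flattened and concatenated (length 2*T*V). Requires imputed,
    normalised tensors; conditions with zero patients are absent."""
    out = {}
    for code, X in tensors_by_condition.items():
        if len(X) == 0:
            continue
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        out[code] = np.concatenate([mean.ravel(), std.ravel()])
    return out


def _retain_top(pairs: list[Edge], retain_fraction: float) -> list[Edge]:
    """Keep the highest-weighted ceil(fraction * n) pairs; ties at the cut
    weight are all retained (deterministic, order-independent)."""
    if not pairs:
        return []
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain fraction must lie in (0, 1]")
    n_keep = max(1, int(np.ceil(retain_fraction * len(pairs))))
    weights = sorted((w for _, _, w in pairs), reverse=True)
    threshold = weights[n_keep - 1]
    return sorted((e for e in pairs if e[2] >= threshold), key=lambda e: (e[0], e[1]))


def record_edges(signatures: dict[str, np.ndarray],
                 retain_fraction: float = 0.5) -> list[Edge]:
    """Symmetric r2 edges from inverse-L2 signature distance, top half kept."""
    codes = sorted(signatures)
    pairs: list[Edge] = []
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            dist = float(np.linalg.norm(signatures[a] - signatures[b]))
            pairs.append((a, b, 1.0 / (1.0 + dist)))
    return _retain_top(pairs, retain_fraction)


def drug_edges(drug_sets: dict[str, set[int]],
               retain_fraction: float = 0.5) -> list[Edge]:
    """Symmetric r3 edges from drug-set Jaccard similarity, top half kept.

    Pairs where both sets are empty are undefined (0/0) and skipped;
    zero-weight (disjoint) pairs are dropped before the retention cut.
    """
    codes = sorted(drug_sets)
    pairs: list[Edge] = []
    n_skipped = 0
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            da, db = drug_sets[a], drug_sets[b]
            union = da | db
            if not union:
                n_skipped += 1
                continue
            w = len(da & db) / len(union)
            if w > 0:
                pairs.append((a, b, w))
    if n_skipped:
        logger.info("drug_edges: skipped %d pairs with two empty drug sets", n_skipped)
    return _retain_top(pairs, retain_fraction)


def assemble_graph(r1: list[Edge], r2: list[Edge], r3: list[Edge],
                   nodes: list[str] | None = None) -> ConditionGraph:
    """Combine the typed edge lists; the node set is the union of endpoints
    plus any extra cohort conditions (isolated nodes allowed)."""
    endpoint_nodes = {n for edges in (r1, r2, r3) for h, t, _ in edges for n in (h, t)}
    if nodes is not None:
        unknown = endpoint_nodes - set(nodes)
        if unknown:
            raise ValueError(f"edges reference unknown conditions: {sorted(unknown)}")
        all_nodes = sorted(nodes)
    else:
        all_nodes = sorted(endpoint_nodes)
    edges = {}
    for rel, lst in zip(RELATIONS, (r1, r2, r3)):
        seen = set()
        for h, t, w in lst:
            if h == t:
                raise ValueError(f"self-loop {h} in {rel}")
            key = (h, t)
            if key in seen or (rel in SYMMETRIC_RELATIONS and (t, h) in seen):
                raise ValueError(f"duplicate edge {key} in {rel}")
            seen.add(key)
        edges[rel] = list(lst)
    return ConditionGraph(all_nodes, edges)


def prune_graph(graph: ConditionGraph, retain_top_fraction: float) -> ConditionGraph:
    """Keep the top fraction of edges by weight within each relation type."""
    if not 0 < retain_top_fraction <= 1:
        raise ValueError("retain_top_fraction must lie in (0, 1]")
    pruned = {rel: _retain_top(lst, retain_top_fraction) if lst else []
              for rel, lst in graph.edges.items()}
    return ConditionGraph(list(graph.nodes), pruned)


def build_condition_graph(diagnosis_records: list[set[str]],
                          tensors_by_condition: dict[str, np.ndarray],
                          drug_sets: dict[str, set[int]],
                          retain_fraction: float = 0.5,
                          nodes: list[str] | None = None) -> ConditionGraph:
    """End-to-end KG construction from preprocessed training-split data."""
    universe = set(nodes) if nodes is not None else set(tensors_by_condition)
    r1 = cooccurrence_edges(diagnosis_records, universe=universe)
    r2 = record_edges({c: s for c, s in
                       condition_signatures(tensors_by_condition).items()
                       if c in universe}, retain_fraction)
    r3 = drug_edges({c: d for c, d in drug_sets.items() if c in universe},
                    retain_fraction)
    return assemble_graph(r1, r2, r3, nodes=sorted(universe))
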
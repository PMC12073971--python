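"""Wang-method GO semantic similarity and best-match-average gene similarity.

The Wang measure scores two GO terms by how much of their ancestor sub-DAGs
they share.  Each term A defines semantic contributions (S-values) over its
ancestors: S_A(A) = 1 and, walking upward, S_A(t) = max over children t' of
t inside A's sub-DAG of w_e * S_A(t'), where w_e is a per-relation weight
(0.8 for is_a, 0.6 for part_of by default).  The similarity of A and B is

    sim(A, B) = sum_{t in common ancestors} (S_A(t) + S_B(t))
                / (SV(A) + SV(B)),

with SV the sum of all S-values of a term.  Gene-gene similarity aggregates
the term-pair block with the best-match average (BMA): the mean of all
row-wise and column-wise maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import GoDag

#: Default per-relation semantic contribution factors of the Wang measure.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GeneSimilarityMatrix:
    """A symmetric gene x gene (or term x term) similarity matrix in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "GeneSimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(frame.index), values=frame.to_numpy(dtype=float))


def _edge_weights(edge_weights: Mapping[str, float] | None) -> dict[str, float]:
    weights = dict(DEFAULT_EDGE_WEIGHTS if edge_weights is None else edge_weights)
    for rel, w in weights.items():
        if not 0.0 < w < 1.0:
            raise ValueError(f"edge weight for {rel!r} must lie in (0, 1), got {w}")
    return weights


def wang_svalues(
    dag: GoDag, term: str, edge_weights: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Semantic contributions of ``term`` over its ancestor sub-DAG.

    Returns a map from every ancestor (the term itself included) to its
    S-value; the anchor has S = 1 and contributions decay multiplicatively
    going up, taking the best (max) path at converging ancestors.
    """
    weights = _edge_weights(edge_weights)
    anchor = dag.resolve(term)

    # Ancestor closure over the core relations.
    ancestors = {anchor}
    stack = [anchor]
    while stack:
        current = stack.pop()
        for pid, _rel in dag.terms[current].parents:
            if pid not in ancestors:
                ancestors.add(pid)
                stack.append(pid)

    # Reverse topological sweep: a term's S-value needs every in-subgraph
    # child placed first; acyclicity guarantees progress each pass.
    svalues = {anchor: 1.0}
    remaining = ancestors - {anchor}
    while remaining:
        placed = []
        for tid in sorted(remaining):
            child_edges = [
                (c, rel)
                for c, rel in dag.children.get(tid, [])
                if c in ancestors
            ]
            if all(c in svalues for c, _ in child_edges):
                svalues[tid] = max(weights[rel] * svalues[c] for c, rel in child_edges)
                placed.append(tid)
        if not placed:  # pragma: no cover - guarded by DAG acyclicity
            raise RuntimeError("cycle encountered in ancestor sub-DAG")
        remaining.difference_update(placed)
    return svalues


def wang_similarity(
    dag: GoDag, a: str, b: str, edge_weights: Mapping[str, float] | None = None
) -> float:
    """Wang similarity between two terms of the same namespace, in [0, 1]."""
    a, b = dag.resolve(a), dag.resolve(b)
    if dag.terms[a].namespace != dag.terms[b].namespace:
        raise ValueError(
            f"cannot compare terms across namespaces: {a} "
            f"({dag.terms[a].namespace}) vs {b} ({dag.terms[b].namespace})"
        )
    sa = wang_svalues(dag, a, edge_weights)
    sb = wang_svalues(dag, b, edge_weights)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    numerator = sum(sa[t] + sb[t] for t in common)
    return numerator / (sum(sa.values()) + sum(sb.values()))


def bma(pair_matrix: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Best-match average of a term-pair similarity block.

    (sum of row maxima + sum of column maxima) / (n_rows + n_cols).
    """
    block = np.asarray(pair_matrix, dtype=float)
    if block.size == 0:
        raise ValueError("BMA of an empty similarity block is undefined")
    if block.ndim != 2:
        raise ValueError("pair matrix must be two-dimensional")
    return float(
        (block.max(axis=1).sum() + block.max(axis=0).sum())
        / (block.shape[0] + block.shape[1])
    )


def term_similarity_matrix(
    terms: Sequence[str], dag: GoDag, edge_weights: Mapping[str, float] | None = None
) -> GeneSimilarityMatrix:
    """Pairwise Wang similarity over a list of same-namespace terms."""
    terms = [dag.resolve(t) for t in terms]
    n = len(terms)
    values = np.eye(n)
    svalues = {t: wang_svalues(dag, t, edge_weights) for t in set(terms)}
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = svalues[terms[i]], svalues[terms[j]]
            common = sa.keys() & sb.keys()
            sim = (
                sum(sa[t] + sb[t] for t in common)
                / (sum(sa.values()) + sum(sb.values()))
                if common
                else 0.0
            )
            values[i, j] = values[j, i] = sim
    return GeneSimilarityMatrix(labels=list(terms), values=values)


def gene_similarity_matrix(
    annotations: Mapping[str, set[str] | Sequence[str]],
    dag: GoDag,
    namespace: str = "biological_process",
    edge_weights: Mapping[str, float] | None = None,
) -> GeneSimilarityMatrix:
    """BMA-aggregated Wang similarity between annotated genes.

    Genes with no annotation inside ``namespace`` are dropped with a warning
    (they carry no semantic information there, matching GOSemSim behavior);
    an unknown term accession is an error.
    """
    kept: dict[str, list[str]] = {}
    dropped = []
    for gene, terms in annotations.items():
        resolved = [dag.resolve(t) for t in terms]
        in_ns = sorted(
            {t for t in resolved if dag.terms[t].namespace == namespace}
        )
        if in_ns:
            kept[gene] = in_ns
        else:
            dropped.append(gene)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene(s) without {namespace} annotations: "
            + ", ".join(sorted(dropped)),
            stacklevel=2,
        )
    if not kept:
        raise ValueError(f"no genes with {namespace} annotations remain")

    all_terms = sorted({t for terms in kept.values() for t in terms})
    term_sim = term_similarity_matrix(all_terms, dag, edge_weights)
    index = {t: i for i, t in enumerate(all_terms)}

    genes = list(kept)
    n = len(genes)
    values = np.eye(n)
    for i in range(n):
        rows = [index[t] for t in kept[genes[i]]]
        for j in range(i + 1, n):
            cols = [index[t] for t in kept[genes[j]]]
            block = term_sim.values[np.ix_(rows, cols)]
            values[i, j] = values[j, i] = bma(block)
    return GeneSimilarityMatrix(labels=genes, values=values)
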
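"""Similarity-matrix clustering and the direct/indirect cluster correlation.

Terms (or genes) are grouped by average-linkage agglomerative clustering on
the distance 1 - similarity, cut at a similarity threshold.  Clusters whose
member names match disease-relevance keywords are labeled *direct*, the rest
*indirect*, and the two groups' normalized COEs score vectors are compared
with a Pearson correlation, cov(DirCl, IndCl) / sqrt(Var(DirCl) Var(IndCl)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .semsim import GeneSimilarityMatrix


@dataclass
class TermCluster:
    cluster_id: int
    members: list[str]
    label: str | None = None  # "direct" | "indirect"
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusterCorrelation:
    """Pearson correlation between paired direct and indirect score vectors."""

    direct: np.ndarray
    indirect: np.ndarray
    cov: float
    var_direct: float
    var_indirect: float
    cor: float
    pairing: str


def cluster_similarity_matrix(
    sim: GeneSimilarityMatrix, cut: float = 0.7
) -> list[TermCluster]:
    """Average-linkage clustering of a similarity matrix.

    Flat clusters are extracted at cophenetic distance 1 - ``cut``; members
    whose average similarity exceeds ``cut`` end up together.  Singletons are
    permitted.  Deterministic given the input label order: clusters are
    numbered by first appearance.
    """
    if not 0.0 < cut < 1.0:
        raise ValueError("cut must lie in (0, 1)")
    values = np.asarray(sim.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        raise ValueError("similarity values must lie in [0, 1]")

    if len(sim.labels) == 1:
        return [TermCluster(cluster_id=1, members=list(sim.labels))]

    distance = 1.0 - (values + values.T) / 2.0
    np.fill_diagonal(distance, 0.0)
    condensed = squareform(distance, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(linkage, t=1.0 - cut, criterion="distance")

    order: dict[int, int] = {}
    members: dict[int, list[str]] = {}
    for label, raw in zip(sim.labels, flat):
        cid = order.setdefault(int(raw), len(order) + 1)
        members.setdefault(cid, []).append(label)
    return [TermCluster(cluster_id=cid, members=members[cid]) for cid in sorted(members)]


def label_direct_indirect(
    clusters: Sequence[TermCluster],
    names: Mapping[str, str],
    keywords: Sequence[str],
) -> list[TermCluster]:
    """Label clusters direct/indirect by case-insensitive keyword match.

    A cluster is *direct* iff at least one member's name contains at least
    one keyword as a substring; all others are *indirect*.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    out = []
    for cluster in clusters:
        hit = any(
            key in names.get(member, "").lower()
            for member in cluster.members
            for key in lowered
        )
        out.append(
            TermCluster(
                cluster_id=cluster.cluster_id,
                members=list(cluster.members),
                label="direct" if hit else "indirect",
                scores=dict(cluster.scores),
            )
        )
    return out


def _scores_array(scores) -> np.ndarray:
    values = list(scores.values()) if isinstance(scores, Mapping) else scores
    return np.asarray(values, dtype=float)


def cluster_correlation(
    direct,
    indirect,
    pairing: Literal["descending", "as_given", "intersection"] = "descending",
) -> ClusterCorrelation:
    """Correlate a direct cluster's scores with an indirect cluster's.

    The two clusters contain different members, so a pairing rule is needed.
    ``"descending"`` (default) sorts both score vectors in descending order,
    truncates to the common length, and pairs positionally — rank k of one
    cluster against rank k of the other.  ``"as_given"`` keeps the input
    order (truncated) and pairs positionally.  ``"intersection"`` pairs
    scores of members present in both clusters (inputs must then be
    mappings).
    """
    if pairing in ("descending", "as_given"):
        d = _scores_array(direct)
        i = _scores_array(indirect)
        if pairing == "descending":
            d, i = np.sort(d)[::-1], np.sort(i)[::-1]
        n = min(d.size, i.size)
        d, i = d[:n], i[:n]
    elif pairing == "intersection":
        if not isinstance(direct, Mapping) or not isinstance(indirect, Mapping):
            raise TypeError("intersection pairing needs member -> score mappings")
        shared = sorted(direct.keys() & indirect.keys())
        d = np.asarray([direct[m] for m in shared], dtype=float)
        i = np.asarray([indirect[m] for m in shared], dtype=float)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    if d.size < 2:
        raise ValueError("need at least 2 paired scores")
    var_d = float(np.var(d, ddof=1))
    var_i = float(np.var(i, ddof=1))
    if var_d == 0 or var_i == 0:
        raise ValueError("zero variance in a paired score vector")
    cov = float(np.cov(d, i, ddof=1)[0, 1])
    return ClusterCorrelation(
        direct=d,
        indirect=i,
        cov=cov,
        var_direct=var_d,
        var_indirect=var_i,
        cor=cov / np.sqrt(var_d * var_i),
        pairing=pairing,
    )
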
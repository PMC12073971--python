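"""Gene Ontology DAG handling.

The Gene Ontology (GO) organizes terms for gene function into three
namespaces (biological_process, molecular_function, cellular_component),
each a rooted directed acyclic graph whose edges point from a child term to
its more general parents via ``is_a`` or ``part_of`` relations.

This module parses OBO files into a :class:`GoDag`, assigns a hierarchy
*level* to every term (longest path from the namespace root, root = 1),
classifies terms as jump (JN), regular (RN) or leaf (LN) nodes according to
where their children sit relative to the next level, and tallies those
categories per level into a reduced-DAG summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Mapping

import networkx as nx
import obonet
import pandas as pd

#: Relations that participate in levels and semantic similarity.
CORE_RELATIONS = ("is_a", "part_of")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class GoTerm:
    """A single GO term with its parent edges.

    ``parents`` holds ``(parent_id, relation)`` pairs restricted to the core
    relations (is_a, part_of); other relationship types are dropped at parse
    time with a warning.
    """

    id: str
    name: str
    namespace: str
    parents: tuple[tuple[str, str], ...] = ()


@dataclass
class GoDag:
    """An acyclic GO term graph with per-namespace roots.

    ``terms`` maps a primary accession to its :class:`GoTerm`; ``alt_ids``
    maps secondary accessions onto primaries; ``children`` is the reverse
    adjacency (parent id -> list of (child id, relation)).
    """

    terms: dict[str, GoTerm]
    roots: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    children: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {tid: [] for tid in self.terms}
            for term in self.terms.values():
                for pid, rel in term.parents:
                    self.children[pid].append((term.id, rel))
        if not self.roots:
            for term in self.terms.values():
                if not term.parents:
                    if term.namespace in self.roots:
                        raise ValueError(
                            f"namespace {term.namespace!r} has multiple roots: "
                            f"{self.roots[term.namespace]}, {term.id}"
                        )
                    self.roots[term.namespace] = term.id

    def resolve(self, term_id: str) -> str:
        """Map an alt_id onto its primary accession (identity for primaries)."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise KeyError(f"unknown GO term {term_id!r}")

    def namespace_terms(self, namespace: str) -> list[str]:
        return [t.id for t in self.terms.values() if t.namespace == namespace]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GoDag):
            return NotImplemented
        return self.terms == other.terms and self.alt_ids == other.alt_ids


def parse_obo(source: str | IO[str]) -> GoDag:
    """Parse OBO 1.2/1.4 text into a :class:`GoDag`.

    Obsolete terms are excluded; ``alt_id`` accessions are mapped onto their
    primary term; relationship types other than is_a/part_of are ignored with
    a warning.  A cycle or a parent reference to an undefined term is a hard
    error.

    Parameters
    ----------
    source
        Path to an OBO file or an open text handle.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)

    dangling = [n for n, data in graph.nodes(data=True) if "name" not in data]
    if dangling:
        raise ValueError(
            "OBO stanzas reference undefined parent term(s): "
            + ", ".join(sorted(dangling))
        )
    if not nx.is_directed_acyclic_graph(graph):
        edge = nx.find_cycle(graph)[0]
        raise ValueError(f"cycle detected in ontology, e.g. edge {edge[0]} -> {edge[1]}")

    ignored: set[str] = set()
    terms: dict[str, GoTerm] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents: list[tuple[str, str]] = []
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in CORE_RELATIONS:
                parents.append((parent, rel))
            else:
                ignored.add(rel)
        terms[node] = GoTerm(
            id=node,
            name=data["name"],
            namespace=data.get("namespace", "biological_process"),
            parents=tuple(sorted(parents)),
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    if ignored:
        warnings.warn(
            f"ignored relationship types: {', '.join(sorted(ignored))}", stacklevel=2
        )
    return GoDag(terms=terms, alt_ids=alt_ids)


def to_obo_text(dag: GoDag, ontology_name: str = "go") -> str:
    """Serialize a :class:`GoDag` back to minimal OBO text.

    Deterministic: stanzas are emitted in sorted accession order so that a
    DAG serializes byte-identically on repeat.  ``parse_obo`` of the output
    reconstructs an equal DAG.
    """
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines += ["[Term]", f"id: {term.id}", f"name: {term.name}",
                  f"namespace: {term.namespace}"]
        for alt, primary in sorted(dag.alt_ids.items()):
            if primary == tid:
                lines.append(f"alt_id: {alt}")
        for pid, rel in term.parents:
            if rel == "is_a":
                lines.append(f"is_a: {pid} ! {dag.terms[pid].name}")
            else:
                lines.append(f"relationship: {rel} {pid} ! {dag.terms[pid].name}")
        lines.append("")
    return "\n".join(lines)


def assign_levels(
    dag: GoDag,
    namespace: str = "biological_process",
    mode: Literal["longest", "shortest"] = "longest",
) -> dict[str, int]:
    """Assign a hierarchy level to every term of one namespace.

    The default convention is longest-path: ``level(t)`` is 1 plus the number
    of edges on the longest directed path from the namespace root down to
    ``t`` (root = 1), so a term always sits strictly below all of its
    parents.  ``mode="shortest"`` swaps the max for a min.
    """
    members = dag.namespace_terms(namespace)
    if not members:
        return {}
    root = dag.roots.get(namespace)
    if root is None:
        raise ValueError(f"namespace {namespace!r} has no root term")

    member_set = set(members)
    sub = nx.DiGraph()
    sub.add_nodes_from(members)
    for tid in members:
        for pid, _rel in dag.terms[tid].parents:
            if pid in member_set:
                sub.add_edge(pid, tid)  # parent -> child

    pick = max if mode == "longest" else min
    levels: dict[str, int] = {}
    for node in nx.topological_sort(sub):
        if node == root:
            levels[node] = 1
            continue
        parent_levels = [levels[p] for p in sub.predecessors(node) if p in levels]
        if parent_levels:
            levels[node] = pick(parent_levels) + 1
    unreachable = member_set - levels.keys()
    if unreachable:
        raise ValueError(
            "terms unreachable from the namespace root: "
            + ", ".join(sorted(unreachable))
        )
    return levels


def categorize_nodes(dag: GoDag, levels: Mapping[str, int]) -> dict[str, str]:
    """Classify each leveled term as ``"JN"``, ``"RN"`` or ``"LN"``.

    LN: no children.  RN: every child sits exactly one level below.  JN: at
    least one child skips a level (child level > own level + 1), i.e. the
    term's descendants "jump" past the next level of the hierarchy.
    """
    categories: dict[str, str] = {}
    for tid in levels:
        kids = [c for c, _rel in dag.children.get(tid, []) if c in levels]
        if not kids:
            categories[tid] = "LN"
        elif all(levels[c] == levels[tid] + 1 for c in kids):
            categories[tid] = "RN"
        else:
            categories[tid] = "JN"
    return categories


def reduce_dag(
    dag: GoDag, levels: Mapping[str, int], categories: Mapping[str, str]
) -> pd.DataFrame:
    """Tally JN/RN/LN counts per hierarchy level (the reduced-DAG summary).

    Returns a DataFrame with columns ``level, jn, rn, ln`` in ascending level
    order; the grand total equals the number of leveled terms.
    """
    rows = []
    for level in sorted(set(levels.values())):
        on_level = [t for t in levels if levels[t] == level]
        rows.append(
            {
                "level": level,
                "jn": sum(categories[t] == "JN" for t in on_level),
                "rn": sum(categories[t] == "RN" for t in on_level),
                "ln": sum(categories[t] == "LN" for t in on_level),
            }
        )
    return pd.DataFrame(rows, columns=["level", "jn", "rn", "ln"]).astype(int)


def terms_on_level(
    terms: Iterable[str], levels: Mapping[str, int], level: int
) -> list[str]:
    """Filter ``terms`` to those assigned to ``level``, preserving order."""
    out = []
    for tid in terms:
        if tid not in levels:
            raise KeyError(f"term {tid!r} has no level assignment")
        if levels[tid] == level:
            out.append(tid)
    return out


def write_reduced_summary(summary: pd.DataFrame, path) -> None:
    """Write a reduced-DAG summary as TSV (columns level, jn, rn, ln)."""
    summary.to_csv(path, sep="\t", index=False)
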
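"""Shared builders for toy GO DAGs used across the suite."""

from __future__ import annotations

import io

import pytest

from coesnet.ontology import GoDag, GoTerm, parse_obo


def make_dag(edges: dict[str, list[tuple[str, str]]], names=None) -> GoDag:
    """Build a GoDag from {term: [(parent, relation), ...]} (single namespace)."""
    names = names or {}
    terms = {
        tid: GoTerm(
            id=tid,
            name=names.get(tid, tid),
            namespace="biological_process",
            parents=tuple(sorted(parents)),
        )
        for tid, parents in edges.items()
    }
    return GoDag(terms=terms)


def gid(k: int) -> str:
    return f"GO:{k:07d}"


@pytest.fixture
def chain_dag() -> GoDag:
    """root <- A <- B via is_a."""
    return make_dag(
        {
            gid(1): [],
            gid(2): [(gid(1), "is_a")],
            gid(3): [(gid(2), "is_a")],
        }
    )


@pytest.fixture
def diamond_dag() -> GoDag:
    """root -> {A, B} -> C."""
    return make_dag(
        {
            gid(1): [],
            gid(2): [(gid(1), "is_a")],
            gid(3): [(gid(1), "is_a")],
            gid(4): [(gid(2), "is_a"), (gid(3), "is_a")],
        }
    )


CHAIN_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: middle process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! middle process
"""


@pytest.fixture
def chain_obo_dag() -> GoDag:
    return parse_obo(io.StringIO(CHAIN_OBO))
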
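"""Synthetic study generator: toy GO DAGs, annotations, and two-group
expression matrices with planted co-annotated modules.

The generator emulates a two-group (cases vs controls) transcriptome design:
module genes share a dedicated GO subtree and receive a mean expression
shift in the case samples, background genes are pure noise, and the DE table
comes from a per-gene two-sample t-test.  Everything is reproducible from
the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import GoDag, GoTerm, to_obo_text

NAMESPACE = "biological_process"


@dataclass
class SyntheticStudy:
    """A generated study: ontology, annotations, expression, DE and truth."""

    dag: GoDag
    annotations: dict[str, set[str]]
    expression: pd.DataFrame  # genes x samples
    de_table: pd.DataFrame  # gene, pvalue, lfc
    truth: dict[str, int | None]  # gene -> planted module id (None = background)
    module_terms: dict[int, list[str]]
    seed: int


def _term_id(k: int) -> str:
    return f"GO:{k:07d}"


def generate_toy_dag(
    seed: int, n_terms: int = 30, max_parents: int = 3, part_of_prob: float = 0.25
) -> tuple[GoDag, str]:
    """A random acyclic single-namespace DAG plus its OBO serialization.

    Term k > 1 draws 1..max_parents distinct parents among terms 1..k-1, so
    the graph is connected and acyclic by construction; each edge is is_a
    with probability 1 - part_of_prob, else part_of.  The OBO text
    round-trips through ``parse_obo`` to an equal DAG and is byte-identical
    for a fixed seed.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, GoTerm] = {}
    root = _term_id(1)
    terms[root] = GoTerm(id=root, name="toy root process", namespace=NAMESPACE)
    for k in range(2, n_terms + 1):
        n_parents = int(rng.integers(1, min(max_parents, k - 1) + 1))
        parent_ks = rng.choice(np.arange(1, k), size=n_parents, replace=False)
        parents = tuple(
            sorted(
                (
                    _term_id(int(p)),
                    "part_of" if rng.random() < part_of_prob else "is_a",
                )
                for p in parent_ks
            )
        )
        tid = _term_id(k)
        terms[tid] = GoTerm(
            id=tid, name=f"toy process {k}", namespace=NAMESPACE, parents=parents
        )
    dag = GoDag(terms=terms)
    return dag, to_obo_text(dag, ontology_name="toy-go")


def generate_synthetic_study(
    seed: int,
    n_genes: int = 200,
    n_samples: int = 20,
    n_modules: int = 3,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    planted_fraction: float = 0.3,
) -> SyntheticStudy:
    """Generate a two-group study with planted co-annotated gene modules.

    ``n_samples`` must be even (half cases, half controls).  Each module
    owns a hub term with a few child terms in a shared toy ontology; module
    genes are annotated to the hub plus subtree terms (so they share >= 1 GO
    term) and shifted by ``effect_size`` in cases.  Background genes draw
    N(0, noise_sd) everywhere and annotate scattered background terms.  The
    DE table carries Welch-free two-sample t-test p-values and the case -
    control mean difference as ``lfc`` (log2-scale units).
    """
    if n_genes < 2 * n_modules:
        raise ValueError("need n_genes >= 2 * n_modules")
    if n_samples % 2 != 0 or n_samples < 4:
        raise ValueError("n_samples must be even and >= 4")
    rng = np.random.default_rng(seed)

    # Ontology: root, per-module hub + 3 children, and background terms.
    subtree_size = 4
    terms: dict[str, GoTerm] = {}
    root = _term_id(1)
    terms[root] = GoTerm(id=root, name="toy root process", namespace=NAMESPACE)
    next_id = 2
    module_terms: dict[int, list[str]] = {}
    for module in range(1, n_modules + 1):
        hub = _term_id(next_id)
        terms[hub] = GoTerm(
            id=hub,
            name=f"module {module} hub process",
            namespace=NAMESPACE,
            parents=((root, "is_a"),),
        )
        owned = [hub]
        for c in range(subtree_size - 1):
            tid = _term_id(next_id + 1 + c)
            terms[tid] = GoTerm(
                id=tid,
                name=f"module {module} child process {c + 1}",
                namespace=NAMESPACE,
                parents=((hub, "is_a"),),
            )
            owned.append(tid)
        module_terms[module] = owned
        next_id += subtree_size
    n_background_terms = max(5, n_genes // 20)
    background_terms = []
    for c in range(n_background_terms):
        tid = _term_id(next_id + c)
        terms[tid] = GoTerm(
            id=tid,
            name=f"background process {c + 1}",
            namespace=NAMESPACE,
            parents=((root, "is_a"),),
        )
        background_terms.append(tid)
    dag = GoDag(terms=terms)

    # Gene membership and annotations.
    module_size = max(2, int(n_genes * planted_fraction / n_modules))
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    truth: dict[str, int | None] = {g: None for g in genes}
    annotations: dict[str, set[str]] = {}
    cursor = 0
    for module in range(1, n_modules + 1):
        for gene in genes[cursor : cursor + module_size]:
            truth[gene] = module
            owned = module_terms[module]
            extra = rng.choice(owned[1:], size=2, replace=False)
            annotations[gene] = {owned[0], *map(str, extra)}
        cursor += module_size
    for gene in genes[cursor:]:
        k = int(rng.integers(1, 4))
        picked = rng.choice(background_terms, size=min(k, len(background_terms)), replace=False)
        annotations[gene] = set(map(str, picked))

    # Expression: half cases, half controls.
    half = n_samples // 2
    samples = [f"case_{i + 1}" for i in range(half)] + [
        f"ctrl_{i + 1}" for i in range(half)
    ]
    matrix = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    planted = np.array([truth[g] is not None for g in genes])
    matrix[planted, :half] += effect_size
    expression = pd.DataFrame(matrix, index=genes, columns=samples)

    # DE table from a per-gene two-sample t-test.
    cases, controls = matrix[:, :half], matrix[:, half:]
    tt = stats.ttest_ind(cases, controls, axis=1)
    de_table = pd.DataFrame(
        {
            "gene": genes,
            "pvalue": tt.pvalue,
            "lfc": cases.mean(axis=1) - controls.mean(axis=1),
        }
    )
    return SyntheticStudy(
        dag=dag,
        annotations=annotations,
        expression=expression,
        de_table=de_table,
        truth=truth,
        module_terms=module_terms,
        seed=seed,
    )
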
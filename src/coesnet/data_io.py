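"""Readers, writers and run configuration.

Formats handled: differential-expression tables and expression matrices as
TSV/CSV, gene-to-GO annotations as GAF 2.2 or two-column TSV, similarity
matrices and cluster tables as TSV, network specifications and training
traces as JSON, and study configuration as YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import TermCluster
from .fnn import FnnNetwork, LayerSpec, TrainState

log = logging.getLogger("coesnet")


@dataclass
class StudyConfig:
    """Thresholds and knobs for one analysis run.

    ``p_cut``/``fc_cut`` gate differential expression (p <= 0.01, natural
    fold change >= 2 by default); ``similarity_cut`` is the clustering
    threshold; ``keywords`` drive direct/indirect labeling; ``seed`` is
    mandatory whenever a stochastic step (permutation test, simulation) runs.
    """

    p_cut: float = 0.01
    fc_cut: float = 2.0
    similarity_cut: float = 0.7
    sim_select_cut: float = 0.5
    keywords: list[str] = field(default_factory=list)
    n_perm: int = 999
    seed: int | None = None
    fnn_tol: float = 1e-4
    fnn_max_epochs: int = 1000

    def __post_init__(self) -> None:
        if self.p_cut <= 0 or self.fc_cut <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic steps")
        return self.seed


def _read_table(path) -> pd.DataFrame:
    """TSV/CSV with sniffed delimiter and locale-independent numerics."""
    return pd.read_csv(path, sep=None, engine="python")


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression table (columns gene, pvalue[, score, lfc])."""
    table = _read_table(path)
    for col in ("gene", "pvalue"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = table["gene"][table["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicated gene id(s): {', '.join(map(str, dup.unique()))}"
        )
    pvals = table["pvalue"].to_numpy(dtype=float)
    bad = (pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)
    if bad.any():
        genes = table["gene"][bad].tolist()
        raise ValueError(
            f"{path}: p-values outside [0, 1] for gene(s): {', '.join(map(str, genes))}"
        )
    return table


def filter_de(
    table: pd.DataFrame, p_cut: float = 0.01, fc_cut: float | None = 2.0
) -> pd.DataFrame:
    """Keep rows with p <= p_cut and |fold change| >= fc_cut.

    The ``lfc`` column is interpreted as log2 fold change; ``fc_cut`` is
    given on the natural scale and compared against ``|lfc| >= log2(fc_cut)``.
    Pass ``fc_cut=None`` to skip the fold-change gate.
    """
    keep = table["pvalue"].to_numpy(dtype=float) <= p_cut
    if fc_cut is not None and fc_cut != 1.0:
        if "lfc" not in table.columns:
            raise ValueError("fold-change filtering requires an 'lfc' column")
        keep &= np.abs(table["lfc"].to_numpy(dtype=float)) >= np.log2(fc_cut)
    out = table[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no genes survive the DE thresholds", stacklevel=2)
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples matrix; first column = gene ids, header = sample ids."""
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 sample columns")
    return frame.astype(float)


def read_annotations(
    path, evidence_codes: Sequence[str] | None = None
) -> dict[str, set[str]]:
    """Read gene -> GO annotations from GAF 2.2 or a two-column TSV.

    GAF rows whose qualifier contains ``NOT`` are skipped; ``evidence_codes``
    optionally whitelists GAF evidence codes (default: accept all).
    """
    gene_terms: dict[str, set[str]] = {}
    wanted = {c.upper() for c in evidence_codes} if evidence_codes else None
    with open(path) as handle:
        first = True
        gaf = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                gaf = gaf or line.startswith("!gaf-version")
                first = False
                continue
            fields = line.split("\t")
            if first:
                first = False
                gaf = gaf or len(fields) >= 15
            if gaf:
                if len(fields) < 7:
                    raise ValueError(f"{path}:{lineno}: truncated GAF row")
                qualifier, gene, term, evidence = (
                    fields[3], fields[1], fields[4], fields[6],
                )
                if "NOT" in qualifier.split("|"):
                    continue
                if wanted is not None and evidence.upper() not in wanted:
                    continue
            else:
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two tab-separated fields "
                        f"(gene, GO id), got {len(fields)}"
                    )
                gene, term = fields
            if not term.startswith("GO:"):
                raise ValueError(f"{path}:{lineno}: malformed GO id {term!r}")
            gene_terms.setdefault(gene, set()).add(term)
    if not gene_terms:
        raise ValueError(f"{path}: no annotations found")
    return gene_terms


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                handle.write(f"{gene}\t{term}\n")


def write_clusters(
    clusters: Sequence[TermCluster], path, names: dict[str, str] | None = None
) -> None:
    """Write clusters as TSV (cluster_id, label, member_id, name, coes, coes_normalized)."""
    names = names or {}
    rows = []
    for cluster in clusters:
        from .scoring import normalize_coes

        norm = normalize_coes(cluster.scores) if cluster.scores else {}
        for member in cluster.members:
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "label": cluster.label or "",
                    "member_id": member,
                    "name": names.get(member, ""),
                    "coes": cluster.scores.get(member, np.nan),
                    "coes_normalized": norm.get(member, np.nan),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def network_to_json(network: FnnNetwork, trace: TrainState | None = None) -> str:
    payload = {
        "layers": [
            {
                "go_level": layer.go_level,
                "terms": [list(t) for t in layer.terms],
                "x": layer.x,
                "w": layer.w,
                "b": layer.b,
            }
            for layer in network.layers
        ],
        "s": network.s,
        "y_predicted": network.y_predicted,
        "y_desired": network.y_desired,
        "e": network.e,
    }
    if trace is not None:
        payload["trace"] = {
            "stop_reason": trace.stop_reason,
            "epochs": [
                {
                    "epoch": rec.epoch,
                    "s": rec.s,
                    "y_predicted": rec.y_predicted,
                    "e": rec.e,
                    "weights": list(rec.weights),
                }
                for rec in trace.history
            ],
        }
    return json.dumps(payload, indent=2)


def network_from_json(text: str) -> FnnNetwork:
    payload = json.loads(text)
    layers = [
        LayerSpec(
            go_level=int(spec["go_level"]),
            terms=tuple((str(t), str(o)) for t, o in spec["terms"]),
            x=float(spec["x"]),
            w=float(spec["w"]),
            b=float(spec["b"]),
        )
        for spec in payload["layers"]
    ]
    return FnnNetwork(layers=layers)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
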
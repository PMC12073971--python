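"""Bundled case-study reference data.

A worked example from a published IgA-nephropathy glomerular transcriptome
study (GEO accession GSE93798) ships with the package: the ranked,
normalized COEs scores of one direct cluster (kidney-development /
immunoglobulin terms) and one indirect cluster (complement-activation /
regulatory terms), the GO term names of both clusters, and the nine-layer
network specification (per-layer input, bias, initial weight and updated
weight over GO levels 5-13, 56 terms in total).  These records are used by
the ``coesnet reproduce`` command, the test suite, and the acceptance
script; the printed weight columns are reference data, not values the
initialization rule reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fnn import FnnNetwork, LayerSpec

# (gene, normalized COEs) of the direct cluster, descending as published.
DIRECT_COES: tuple[tuple[str, float], ...] = (
    ("GATA3", 1.00), ("EGR1", 0.86), ("CTNNB1", 0.85), ("VEGFA", 0.79),
    ("STAT1", 0.78), ("FGFR2", 0.78), ("TGFB2", 0.76), ("PAX8", 0.75),
    ("AGTR1", 0.70), ("COL4A3", 0.70), ("WWTR1", 0.69), ("SUPT6H", 0.68),
    ("NF1", 0.66), ("CFLAR", 0.62), ("ATM", 0.60), ("PBX1", 0.59),
    ("ADAMTS1", 0.58), ("MTSS1", 0.57), ("SAMHD1", 0.56), ("DLG1", 0.56),
    ("PECAM", 0.56), ("TFRC", 0.55), ("PDGFD", 0.55), ("CEP290", 0.48),
    ("ARID5B", 0.47), ("RNF168", 0.37), ("NID1", 0.31), ("EXOSC3", 0.10),
)

# (gene, normalized COEs) of the indirect cluster, descending as published.
INDIRECT_COES: tuple[tuple[str, float], ...] = (
    ("AKT2", 1.00), ("GSK3B", 1.00), ("VEGFA", 0.94), ("SIK1", 0.93),
    ("OGT", 0.93), ("DHX9", 0.91), ("MDM2", 0.90), ("THBS1", 0.90),
    ("NR1H4", 0.86), ("CD74", 0.86), ("PRKAA1", 0.85), ("PDE4D", 0.80),
    ("RB1", 0.80), ("NF1", 0.79), ("CD46", 0.77), ("KMT2A", 0.75),
    ("ENG", 0.75), ("ZFP36", 0.73), ("VAV3", 0.72), ("HIP1", 0.71),
    ("COL4A3", 0.64), ("CR1", 0.62), ("TASOR", 0.50), ("CFI", 0.44),
    ("SMC3", 0.31), ("RPS27L", 0.23), ("SMC1A", 0.20), ("ICE2", 0.17),
)

#: GO term names of the direct (kidney-development) cluster.
DIRECT_TERM_NAMES: dict[str, str] = {
    "GO:0090183": "regulation of kidney development",
    "GO:0072111": "cell proliferation involved in kidney development",
    "GO:0032835": "glomerulus development",
    "GO:0072110": "glomerular mesangial cell proliferation",
    "GO:0001822": "kidney development",
    "GO:0072012": "glomerulus vasculature development",
    "GO:0090192": "regulation of glomerulus development",
    "GO:0072109": "glomerular mesangium development",
    "GO:0061440": "kidney vasculature development",
    "GO:0072079": "nephron tubule formation",
    "GO:0072234": "metanephric nephron tubule development",
    "GO:0072203": "cell proliferation involved in metanephros development",
    "GO:0072088": "nephron epithelium morphogenesis",
    "GO:0072028": "nephron morphogenesis",
    "GO:0072073": "kidney epithelium development",
    "GO:0060993": "kidney morphogenesis",
    "GO:0072243": "metanephric nephron epithelium development",
    "GO:0061217": "regulation of mesonephros development",
    "GO:0072273": "metanephric nephron morphogenesis",
    "GO:0072210": "metanephric nephron development",
    "GO:0072078": "nephron tubule morphogenesis",
    "GO:0001656": "metanephros development",
    "GO:0002200": "somatic diversification of immune receptors",
    "GO:0002208": "somatic diversification of immunoglobulins involved in immune response",
    "GO:0003338": "metanephros morphogenesis",
    "GO:0016445": "somatic diversification of immunoglobulins",
    "GO:0001823": "mesonephros development",
    "GO:0072224": "metanephric glomerulus development",
    "GO:0016446": "somatic hypermutation of immunoglobulin genes",
    "GO:0002566": "somatic diversification of immune receptors mutation",
    "GO:0072074": "kidney mesenchyme development",
    "GO:0072010": "glomerular epithelium development",
}

#: GO term names of the indirect (complement/regulation) cluster.
INDIRECT_TERM_NAMES: dict[str, str] = {
    "GO:0006956": "complement activation",
    "GO:0035278": "miRNA mediated inhibition of translation",
    "GO:0040033": "negative regulation of translation, ncRNA-mediated",
    "GO:0045974": "regulation of translation, ncRNA-mediated",
    "GO:0010676": "positive regulation of cellular carbohydrate metabolic process",
    "GO:0042304": "regulation of fatty acid biosynthetic process",
    "GO:2000257": "regulation of protein activation cascade",
    "GO:1903317": "regulation of protein maturation",
    "GO:0070613": "regulation of protein processing",
    "GO:0090218": "positive regulation of lipid kinase activity",
    "GO:0006919": "activation of cysteine-type endopeptidase activity involved in apoptotic process",
    "GO:1900745": "positive regulation of p38MAPK cascade",
    "GO:0000083": "regulation of transcription transition of mitotic involved in G1/S cell cycle",
    "GO:0044030": "regulation of DNA methylation",
    "GO:2000765": "regulation of cytoplasmic translation",
    "GO:0050994": "regulation of lipid catabolic process",
    "GO:0090329": "regulation of DNA-dependent DNA replication",
    "GO:0033137": "negative regulation of peptidyl-serine phosphorylation",
    "GO:0045761": "regulation of adenylate cyclase activity",
    "GO:1902932": "positive regulation of collagen metabolic process",
    "GO:0006346": "methylation-dependent chromatin silencing",
    "GO:0043255": "regulation of carbohydrate biosynthetic process",
    "GO:0006111": "regulation of gluconeogenesis",
    "GO:1903727": "positive regulation of phospholipid metabolic process",
    "GO:0006359": "regulation of transcription by RNA polymerase III",
}


@dataclass(frozen=True)
class ReferenceLayer:
    """One published network layer: GO level, terms with origin, x/b/w columns."""

    go_level: int
    terms: tuple[tuple[str, str], ...]
    x: float
    b: float
    w: float
    w_updated: float


def _d(*ids: str) -> tuple[tuple[str, str], ...]:
    return tuple((i, "direct") for i in ids)


def _i(*ids: str) -> tuple[tuple[str, str], ...]:
    return tuple((i, "indirect") for i in ids)


REFERENCE_LAYERS: tuple[ReferenceLayer, ...] = (
    ReferenceLayer(5, _i("GO:0045761"), 0.79, 0.01, 0.49, 0.49),
    ReferenceLayer(
        6,
        _d("GO:0002200")
        + _i("GO:2000257", "GO:1903317", "GO:0050994", "GO:0043255"),
        0.66, 0.08, 0.70, 0.70,
    ),
    ReferenceLayer(
        7,
        _d("GO:0001822", "GO:0016445", "GO:0002566")
        + _i("GO:0006956", "GO:0010676", "GO:0070613", "GO:1902932"),
        0.64, 0.12, 0.91, 0.75,
    ),
    ReferenceLayer(
        8,
        _d(
            "GO:0090183", "GO:0072111", "GO:0072073", "GO:0060993",
            "GO:0001656", "GO:0002208", "GO:0001823", "GO:0016446",
            "GO:0072074",
        )
        + _i("GO:0006111", "GO:1903727"),
        0.74, 0.19, 0.93, 0.82,
    ),
    ReferenceLayer(
        9,
        _d("GO:0032835", "GO:0061440", "GO:0072203", "GO:0072028")
        + _i("GO:0045974")
        + _d("GO:0061217", "GO:0003338")
        + _i("GO:0042304", "GO:2000765", "GO:0090329"),
        0.70, 0.19, 0.83, 0.89,
    ),
    ReferenceLayer(
        10,
        _d("GO:0072012", "GO:0090192", "GO:0072088", "GO:0072243", "GO:0072224")
        + _i("GO:0040033")
        + _d("GO:0072273", "GO:0072010")
        + _i("GO:0090218", "GO:0044030"),
        0.72, 0.17, 0.69, 0.84,
    ),
    ReferenceLayer(
        11,
        _d("GO:0072109", "GO:0072234")
        + _i("GO:0035278", "GO:0033137")
        + _d("GO:0072078")
        + _i("GO:0000083", "GO:0006359"),
        0.71, 0.12, 0.37, 0.79,
    ),
    ReferenceLayer(12, _d("GO:0072110", "GO:0072079"), 0.77, 0.03, 0.21, 0.66),
    ReferenceLayer(
        13, _i("GO:0006919", "GO:1900745", "GO:0006346"), 0.60, 0.05, 0.1, 0.59
    ),
)


def case_study_coes() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The direct and indirect clusters' ranked COEs tables (28 rows each)."""
    direct = pd.DataFrame(DIRECT_COES, columns=["gene", "coes"])
    indirect = pd.DataFrame(INDIRECT_COES, columns=["gene", "coes"])
    return direct, indirect


def case_study_term_names() -> dict[str, str]:
    """GO id -> name for both bundled clusters (57 terms)."""
    return {**DIRECT_TERM_NAMES, **INDIRECT_TERM_NAMES}


def case_study_layers() -> list[ReferenceLayer]:
    return list(REFERENCE_LAYERS)


def case_study_network(weights: str = "initial") -> FnnNetwork:
    """Build the nine-layer network from the bundled columns verbatim.

    ``weights="initial"`` uses the published initial weight column,
    ``"updated"`` the published post-update column.
    """
    if weights not in ("initial", "updated"):
        raise ValueError("weights must be 'initial' or 'updated'")
    layers = [
        LayerSpec(
            go_level=ref.go_level,
            terms=ref.terms,
            x=ref.x,
            w=ref.w if weights == "initial" else ref.w_updated,
            b=ref.b,
        )
        for ref in REFERENCE_LAYERS
    ]
    return FnnNetwork(layers=layers)
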
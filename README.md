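# coesnet

Ontology-weighted gene selection and interaction-module discovery for
two-group transcriptome studies.

Differential-expression (DE) analysis of case/control expression data — for
example glomerular biopsy cohorts in IgA nephropathy and C3 glomerulopathy —
produces long gene lists with highly redundant Gene Ontology (GO) content.
`coesnet` implements a scoring scheme that corrects expression evidence with
ontology structure so that genes are prioritized not only by how strongly
they change, but by how coherently their biological context hangs together:

- **Wang semantic similarity + BMA.** Term–term similarity over the GO DAG
  with per-relation contribution weights (0.8 `is_a`, 0.6 `part_of`),
  aggregated to gene–gene similarity with the best-match average.
- **Msimsc.** A pairwise group statistic,
  `Msimsc = Σ_{i<j} ½(δ_i²/δ_j² + δ_j²/δ_i²) · ((μ_i+μ_j)/2)²`,
  with a Shapiro–Wilk normality screen and a one-sided permutation null
  (columns shuffled across rows, add-one-corrected p).
- **COEs.** The combined score `MCombSc = n_expr·M_expr + n_sel·M_simsc`
  joining DE evidence (`M_expr = −log10 p` by default) with
  similarity-matrix support, min–max normalized per cluster.
- **Direct/indirect clusters.** Average-linkage clustering of the similarity
  matrix, keyword-based labeling (e.g. "kidney", "complement"), and the
  Pearson correlation `Cor(DirCl, IndCl) = cov/√(Var·Var)` between the two
  groups' descending-paired score vectors.
- **Reduced GO DAG.** Per-term hierarchy levels (longest path from the root,
  root = 1) and jump/regular/leaf node (JN/RN/LN) categories, tallied per
  level.
- **Hierarchy-initialized FNN.** One layer per GO level across a
  direct+indirect cluster pair; biases = per-level term fractions, weights =
  normalized mean levels; forward pass `y = σ(Σ w·x + b)`, squared-Euclidean
  loss, and a bespoke gradient-free update `w ← σ(x·w) + s·‖y_d − y_p‖`.

A synthetic-study generator (toy DAGs, annotations, planted co-annotated
modules with a case-group mean shift) makes the whole pipeline testable
without external downloads.

## Worked example

```python
from coesnet import clustering, fixtures, fnn

# Bundled case study: a direct (kidney-development) and an indirect
# (complement/regulation) cluster, 28 ranked COEs scores each.
direct, indirect = fixtures.case_study_coes()
cor = clustering.cluster_correlation(direct["coes"], indirect["coes"])
print(f"{cor.cor:.4f}")            # 0.9284

# Nine-layer network over GO levels 5-13 (56 terms).
s, y = fnn.forward(fixtures.case_study_network("initial").layers)
print(f"{s:.4f} {y:.4f}")          # 4.6419 0.9905

s, y = fnn.forward(fixtures.case_study_network("updated").layers)
print(f"{s:.4f} {y:.4f}")          # 5.5468 0.9961
```

The correlation of 0.9284 says the two clusters' ranked score profiles are
strongly associated — the indirect (regulatory) cluster mirrors the
disease-proximal one, which is the signal used as the desired network
output.  The forward passes give the module probability before (0.9905) and
after (0.9961) one weight update.

The same numbers print from the command line via `coesnet reproduce`; a
full synthetic run looks like

```sh
coesnet simulate --seed 1 --out-dir study/
coesnet simsim --obo study/ontology.obo --annotations study/annotations.tsv --out study/sim.tsv
coesnet score --de study/de_table.tsv --sim study/sim.tsv --out study/coes.tsv
```

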
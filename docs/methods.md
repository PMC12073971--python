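# Methods

## The model

`coesnet` treats gene prioritization as a correction problem: expression
evidence from a two-group (case/control) design is adjusted by how
semantically coherent a gene's GO context is. The pipeline is

1. gene–gene semantic similarity (Wang + BMA),
2. the pairwise group statistic Msimsc with a permutation null,
3. the combined score MCombSc per gene, normalized per cluster,
4. direct/indirect cluster labeling and their score correlation,
5. GO-DAG level reduction, and
6. a small feed-forward network whose parameters are initialized from the
   hierarchy itself.

## Semantic similarity

The Wang measure assigns each anchor term A semantic contributions over its
ancestor sub-DAG: S_A(A) = 1 and S_A(t) = max over in-sub-DAG children t′ of
w_e · S_A(t′), with w_e the relation weight. Defaults are the measure's
conventional 0.8 (`is_a`) and 0.6 (`part_of`); both are configurable, and
regulates-type edges are parsed but excluded from both levels and
similarity. sim(A,B) sums S_A + S_B over shared ancestors and normalizes by
the two SV totals, so it lies in [0, 1] and equals 1 at identity. Gene-level
similarity is the best-match average of the term-pair block. Genes with no
annotation in the requested namespace are dropped (scoring them 0 would
conflate "unknown" with "dissimilar").

Implementation notes: S-values are computed by a reverse topological sweep
over the ancestor closure; the namespace root participates and contributes
its S-values, per the original formulation. The test suite checks the sweep
against an independent top-down recursion and a brute-force double loop.

## Msimsc and its null

The statistic sums, over all unordered pairs of rows of a groups × samples
matrix, ½(δ₁²/δ₂² + δ₂²/δ₁²)·((μ₁+μ₂)/2)². Reading the double sum as
unordered pairs i < j is the only interpretation consistent with "every
pair of groups". δ uses the n−1 denominator. A zero δ makes the ratio term
undefined; this is a hard error rather than an epsilon regularization,
because silently inflating degenerate rows would bias the permutation null.
Callers pre-filter constant rows.

The null permutes each sample column independently across rows, which
preserves per-sample marginals (column sums are invariant) while destroying
group identity; a global entry shuffle is available as `mode="global"`.
Row-label shuffling is *not* offered: Msimsc is symmetric in the rows, so
relabeling them is a no-op and cannot form a null. Degenerate replicates
(zero-δ rows after shuffling) are resampled and counted; more than 50%
degenerate aborts. p = (1 + #{null ≥ observed}) / (n_perm + 1), the add-one
correction, so p is never 0 and is super-uniform under the null (verified
empirically in the acceptance suite: 200 i.i.d.-row matrices, n_perm = 199,
fraction of p ≤ 0.05 required to stay ≤ 0.08).

The Shapiro–Wilk screen (pass ⇔ p > 0.05) is advisory: failing rows warn
but are not excluded, since mild deviations barely affect the permutation
test, which does not rely on normality.

## The combined score

MCombSc = n_expr·M_expr + n_sel·M_simsc, exactly, with no hidden
normalization. The expression score M_expr is −log10(p) of the DE test by
default (a precomputed `score` column is honored when present); n_expr is
the number of genes passing the p ≤ 0.01 cutoff. For the per-gene pipeline,
n_sel counts similarity-matrix neighbors at sim ≥ 0.5 and M_simsc is their
mean similarity — the per-gene reading of the similarity component is a
package design choice, as only the cluster-level statistic is fully
specified upstream of it. Per-cluster normalization is min–max, so each
cluster's top gene scores 1.00 and a constant cluster maps to all-1.

DE filtering uses p ≤ 0.01 and natural fold change ≥ 2 by default, with the
`lfc` column interpreted on the log2 scale (|lfc| ≥ log2(fc)).

## Clusters and their correlation

The similarity matrix is clustered by average-linkage agglomeration on
distance 1 − sim, cut at similarity 0.7 by default. A binary-cut style
clusterer would serve equally; the downstream math only needs a partition,
so the standard scipy linkage is used deliberately. Clusters are labeled
*direct* when any member's term name contains a disease keyword
(case-insensitive substring), else *indirect*.

The direct–indirect correlation is Pearson (literally cov/√(Var·Var)).
Because the two clusters hold different genes, a pairing rule is required:
the default sorts both score vectors descending, truncates to the common
length, and pairs by rank — the only rule computable from two ranked score
columns alone. Member-intersection pairing and as-given positional pairing
are alternative modes. Note that under rank pairing antisymmetric inputs
(v vs −v) do not correlate at −1; that identity only holds for as-given
pairing, which is why both modes exist.

On the bundled 28+28 case-study score vectors the rank-paired Pearson
correlation is 0.9284. The published two-decimal value is 0.92; the
recomputed value agrees within one unit in the last printed digit (the
acceptance test's tolerance), though it rounds to 0.93 — consistent with
the source values themselves being printed at two decimals.

## GO-DAG levels and reduction

Level = 1 + length of the longest directed path from the namespace root
(root = 1). Longest-path matches the behavior of the R tooling this mirrors
and guarantees level(child) ≥ level(parent) + 1 on every edge; a
shortest-path mode exists but is not the default. Node categories: LN = no
children; RN = every child exactly one level below; JN = at least one child
skips a level. The reduced-DAG summary tallies the three categories per
level; totals conserve the namespace size.

## The network

One layer per GO level present in a direct+indirect cluster pair, ascending.
Initialization is hierarchy-derived, not random:

- bias b_l = (#terms at level l) / (total terms across both clusters), so
  the bias vector sums to 1 (a conservation invariant under test);
- weight w_l = (mean GO level of the layer's terms) / (max level present),
  keeping weights in (0, 1]; a raw-mean mode is available;
- input x_l = mean normalized COEs of the genes annotated to the layer's
  terms (0 with a warning when no gene touches a layer).

The forward pass collapses all layers into a single pre-activation
s = Σ(w·x + b) followed by one logistic sigmoid. This scalar-collapse
architecture is what the bundled nine-layer worked example computes
(s = 4.6419 → y = 0.9905 with the initial weights; s = 5.5468 → y = 0.9961
with the updated ones), and the implementation follows that computation
rather than a wider multi-neuron topology. The bundled weight columns are
reference data: they are not derivable from the initialization rule, whereas
the bias column is reproduced by the term-count rule to within 0.01 on 8 of
9 layers (the two ten-term layers are mutually ambiguous).

Loss is E = ½‖y_d − y_p‖²; the plain distance ‖y_d − y_p‖ is reported
alongside since it is the quantity usually quoted as "error" (0.0057
between the two bundled passes). The update rule is gradient-free:
w_new = σ(x·w) + s·‖y_d − y_p‖ applied per layer with the shared s and
error norm — the only dimension-consistent elementwise reading. With zero
error it reduces to w_new = σ(x·w). Training iterates forward → loss →
update until E < tol (default 1e−4), the loss stalls for 5 consecutive
epochs, or max_epochs (default 1000); there is no randomness, so training
is exactly reproducible. The sigmoid derivative is computed as
e^(−|s|)/(1+e^(−|s|))², which is symmetric and stays strictly positive up
to the exp underflow near |s| ≈ 745.

## Synthetic studies

The generator emulates a two-group microarray/RNA-seq contrast: n_genes
genes × n_samples samples (half cases, half controls), background
expression N(0, noise_sd), and n_modules planted modules whose genes (30%
of the genome, split evenly) share a dedicated GO subtree (a hub term plus
three children) and receive a +effect_size mean shift in cases. The DE
table is a per-gene two-sample t-test; `lfc` is the case − control mean
difference on log2-scale units. Defaults — 200 genes, 20 samples, 3
modules, effect 3, noise 1 — are the conditions under which the planted
modules are comfortably detectable (>80% of planted genes at p ≤ 0.01) and
are the conditions used for the module-recovery acceptance check
(AUC > 0.9 by MCombSc). Problem sizes throughout the suite (toy DAGs of
12–50 terms, 200-gene studies, 199–999 permutations) were chosen as the
smallest at which each property is statistically meaningful.

What the generator does not emulate: probe-level noise and normalization
artifacts, correlated background genes, annotation incompleteness and
evidence-code heterogeneity, and overlapping modules. Passing tests
demonstrate internal correctness and detectability under clean planted
signal, not performance on real cohorts.

## Known limitations

- The per-gene similarity component of MCombSc (n_sel, mean neighbor
  similarity at ≥ 0.5) is one of several defensible readings; the cutoff is
  exposed as a parameter.
- Keyword labeling is substring matching, not concept matching; synonyms
  must be supplied explicitly.
- The bespoke weight update has no convergence guarantee; the stall
  detector and epoch cap are the safeguards, and the full trace is recorded
  for inspection.
- Information-content similarity measures (Resnik, Lin) and cross-namespace
  composites are out of scope.
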
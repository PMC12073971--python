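"""COEs statistics: the Msimsc pairwise statistic, its permutation null,
the combined ontology-expression score, and supporting diagnostics.

Msimsc compares every unordered pair of groups (rows of a groups x samples
matrix) through a variance-ratio times squared-mean-average term

    pair(i, j) = 1/2 (d_i^2/d_j^2 + d_j^2/d_i^2) * ((m_i + m_j)/2)^2

with m the group mean and d the sample standard deviation (n-1 denominator),
and sums the terms over all pairs.  A one-sided permutation test compares the
observed statistic against a null built by shuffling each sample column
across groups.  The combined score MCombSc = nexpr*Mexpr + nsel*Msimsc ranks
genes by joining expression evidence with similarity-matrix support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStats",
    "MsimscResult",
    "PermutationResult",
    "CoesScore",
    "group_stats",
    "pair_term",
    "msimsc",
    "shapiro_screen",
    "permutation_test",
    "coes_combine",
    "normalize_coes",
    "mean_vif",
    "score_genes",
]


@dataclass(frozen=True)
class GroupStats:
    group: str
    mu: float
    delta: float  # sample standard deviation, n-1 denominator
    n: int


@dataclass
class MsimscResult:
    value: float
    n_pairs: int
    contributions: list[tuple[int, int, float]]


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    n_degenerate: int = 0


@dataclass(frozen=True)
class CoesScore:
    """One gene's combined ontology-expression score and its components."""

    m_comb: float
    n_expr: int
    m_expr: float
    n_sel: int
    m_simsc: float


def _as_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D groups x samples matrix")
    return arr


def group_stats(
    matrix, groups: Sequence[str] | None = None
) -> list[GroupStats]:
    """Per-row mean and sample standard deviation (row order preserved)."""
    arr = _as_matrix(matrix)
    names = list(groups) if groups is not None else [str(i) for i in range(len(arr))]
    out = []
    for i, row in enumerate(arr):
        if row.size < 2 or not np.all(np.isfinite(row)):
            raise ValueError(f"row {names[i]!r} needs >= 2 finite values")
        out.append(
            GroupStats(
                group=names[i],
                mu=float(row.mean()),
                delta=float(row.std(ddof=1)),
                n=row.size,
            )
        )
    return out


def pair_term(mu1: float, mu2: float, delta1: float, delta2: float) -> float:
    """One pair's Msimsc contribution; requires both deltas strictly positive."""
    if delta1 <= 0 or delta2 <= 0:
        raise ValueError("degenerate group variance: delta must be > 0")
    v1, v2 = delta1**2, delta2**2
    return 0.5 * (v1 / v2 + v2 / v1) * ((mu1 + mu2) / 2.0) ** 2


def _msimsc_value(mu: np.ndarray, delta: np.ndarray) -> float:
    """Vectorized sum of pair terms over all unordered row pairs."""
    var = delta**2
    ratio = 0.5 * (var[:, None] / var[None, :] + var[None, :] / var[:, None])
    means = ((mu[:, None] + mu[None, :]) / 2.0) ** 2
    terms = ratio * means
    iu = np.triu_indices(len(mu), k=1)
    return float(terms[iu].sum())


def msimsc(matrix) -> MsimscResult:
    """The pairwise dis/similarity statistic over all unordered row pairs."""
    arr = _as_matrix(matrix)
    if arr.shape[0] < 2:
        raise ValueError("Msimsc needs at least 2 rows (no pairs otherwise)")
    gstats = group_stats(arr)
    contributions = []
    total = 0.0
    for i in range(len(gstats)):
        for j in range(i + 1, len(gstats)):
            try:
                term = pair_term(
                    gstats[i].mu, gstats[j].mu, gstats[i].delta, gstats[j].delta
                )
            except ValueError as exc:
                raise ValueError(f"pair ({i}, {j}): {exc}") from exc
            contributions.append((i, j, term))
            total += term
    return MsimscResult(value=total, n_pairs=len(contributions), contributions=contributions)


def shapiro_screen(matrix, alpha: float = 0.05, groups=None) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per row.

    Returns a DataFrame (group, w, p, passed); rows whose test is undefined
    (constant values, n outside [3, 5000]) are flagged failed rather than
    raising, since the screen is advisory.
    """
    arr = _as_matrix(matrix)
    names = list(groups) if groups is not None else [str(i) for i in range(len(arr))]
    rows = []
    for name, row in zip(names, arr):
        w = p = np.nan
        passed = False
        if 3 <= row.size <= 5000 and np.ptp(row) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.shapiro(row)
            w, p = float(res.statistic), float(res.pvalue)
            passed = p > alpha
        rows.append({"group": name, "w": w, "p": p, "passed": passed})
    return pd.DataFrame(rows)


def permutation_test(
    matrix,
    n_perm: int = 999,
    seed: int = 0,
    mode: Literal["within_columns", "global"] = "within_columns",
) -> PermutationResult:
    """One-sided permutation test for Msimsc.

    The default null shuffles each sample column independently across rows,
    preserving per-sample marginals while destroying group identity;
    ``mode="global"`` shuffles all entries of the matrix.  Replicates whose
    permuted matrix has a zero-variance row are resampled and counted; more
    than 50% degenerate draws is an error.  p uses the add-one correction
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    arr = _as_matrix(matrix)
    observed = msimsc(arr).value
    rng = np.random.default_rng(seed)

    null = np.empty(n_perm)
    degenerate = 0
    collected = 0
    max_attempts = 2 * n_perm
    attempts = 0
    while collected < n_perm:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "more than 50% of permutation replicates were degenerate "
                "(zero-variance rows); pre-filter constant structure"
            )
        if mode == "within_columns":
            perm = rng.permuted(arr, axis=0)
        else:
            perm = rng.permutation(arr.ravel()).reshape(arr.shape)
        delta = perm.std(axis=1, ddof=1)
        if np.any(delta == 0):
            degenerate += 1
            continue
        null[collected] = _msimsc_value(perm.mean(axis=1), delta)
        collected += 1
    if degenerate:
        warnings.warn(
            f"resampled {degenerate} degenerate permutation replicate(s)",
            stacklevel=2,
        )
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        n_degenerate=degenerate,
    )


def coes_combine(n_expr: int, m_expr: float, n_sel: int, m_simsc: float) -> CoesScore:
    """MCombSc = nexpr * Mexpr + nsel * Msimsc, exactly, components retained."""
    for name, count in (("n_expr", n_expr), ("n_sel", n_sel)):
        if int(count) != count or count < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {count!r}")
    if not (np.isfinite(m_expr) and np.isfinite(m_simsc)):
        raise ValueError("scores must be finite")
    return CoesScore(
        m_comb=int(n_expr) * float(m_expr) + int(n_sel) * float(m_simsc),
        n_expr=int(n_expr),
        m_expr=float(m_expr),
        n_sel=int(n_sel),
        m_simsc=float(m_simsc),
    )


def normalize_coes(scores: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize one cluster's scores so the maximum maps to 1.0.

    A constant cluster maps to all-1 (every member is equally the top).
    """
    if not scores:
        raise ValueError("cannot normalize an empty cluster")
    values = np.asarray(list(scores.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {g: 1.0 for g in scores}
    return {g: float((v - lo) / (hi - lo)) for g, v in scores.items()}


def mean_vif(features) -> float:
    """Mean variance inflation factor across feature columns.

    VIF_j = 1/(1 - R^2_j) from an ordinary least-squares regression of
    feature j on the remaining features (with intercept).  Near-singular fits
    are capped at 1e6 with a warning instead of raising, so an exactly
    collinear pair degrades gracefully.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant

    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a samples x features matrix with >= 2 features")
    if arr.shape[0] <= arr.shape[1]:
        raise ValueError("need more samples than features")
    exog = add_constant(arr, has_constant="add")
    cap = 1e6
    vifs = []
    capped = []
    for j in range(1, exog.shape[1]):  # skip the intercept column
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vif = variance_inflation_factor(exog, j)
        if not np.isfinite(vif) or vif > cap:
            capped.append(j - 1)
            vif = cap
        vifs.append(vif)
    if capped:
        warnings.warn(
            f"(near-)collinear feature(s) {capped}; VIF capped at {cap:g}",
            stacklevel=2,
        )
    return float(np.mean(vifs))


def score_genes(
    de_table: pd.DataFrame,
    sim,
    p_cut: float = 0.01,
    sim_cut: float = 0.5,
) -> pd.DataFrame:
    """Per-gene combined ontology-expression scores.

    For each gene: Mexpr = the table's ``score`` column if present, else
    -log10(pvalue); nexpr = the number of genes passing ``p_cut`` (shared
    across genes); nsel = the number of other genes whose semantic similarity
    to this gene is >= ``sim_cut``; Msimsc component = the mean of those
    similarities (0 when the gene has no similarity support).  Returns the
    table sorted by m_comb descending.
    """
    genes = list(de_table["gene"])
    pvals = de_table["pvalue"].to_numpy(dtype=float)
    if "score" in de_table.columns:
        m_expr = de_table["score"].to_numpy(dtype=float)
    else:
        m_expr = -np.log10(np.clip(pvals, 1e-300, None))
    n_expr = int(np.sum(pvals <= p_cut))

    label_index = {g: i for i, g in enumerate(sim.labels)} if sim is not None else {}
    rows = []
    for gene, me in zip(genes, m_expr):
        n_sel, m_simsc = 0, 0.0
        if gene in label_index:
            i = label_index[gene]
            sims = np.delete(sim.values[i], i)
            selected = sims[sims >= sim_cut]
            n_sel = int(selected.size)
            m_simsc = float(selected.mean()) if n_sel else 0.0
        score = coes_combine(n_expr, float(me), n_sel, m_simsc)
        rows.append(
            {
                "gene": gene,
                "m_expr": score.m_expr,
                "n_expr": score.n_expr,
                "n_sel": score.n_sel,
                "m_simsc": score.m_simsc,
                "m_comb": score.m_comb,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("m_comb", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
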
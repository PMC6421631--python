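"""Differential expression of siMyb vs siNEG and transcriptome summaries.

The pipeline is a deliberately small negative-binomial workflow: libraries
are normalised by the median-of-ratios estimator, a per-gene NB dispersion
is estimated by method of moments on normalised counts (pooled across the
two conditions after removing the condition means) and then moderated
empirical-Bayes style toward the across-gene median with a prior weight of
``DISPERSION_PRIOR_DF`` pseudo-degrees of freedom — with 3-vs-3 designs the
raw gene-wise moment estimate is far too noisy to plug into a Wald
statistic.  The Wald test on the log2 fold change uses the moderated
standard error and a t reference with prior + residual degrees of freedom.
Benjamini-Hochberg adjustment is applied across all tested genes of a
contrast.

Also here: FPKM quantification, Spearman correlation clustering of samples,
hierarchical clustering of per-cell-line fold changes, and Venn region
cardinalities for differentially expressed gene sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io_formats import CountTable, GeneModel

__all__ = [
    "DEResult",
    "size_factors",
    "nb_test",
    "nb_test_all",
    "call_de",
    "bh_adjust",
    "fpkm",
    "spearman_cluster",
    "cluster_log2fc",
    "venn_overlaps",
]

DISPERSION_FLOOR = 1e-8
DISPERSION_PRIOR_DF = 10.0
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p_value: float
    q_value: float
    call: str  # down | up | ns
    tested: bool = True


def size_factors(table: CountTable | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    estimator (standard median-of-ratios behaviour); all genes are still
    eligible for testing downstream.
    """
    counts = table.matrix if isinstance(table, CountTable) else np.asarray(table)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; filter the count "
            "table before estimating size factors"
        )
    sub = counts[positive].astype(float)
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    return factors / np.exp(np.log(factors).mean())


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def _wald_nb(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised NB Wald test over genes (rows). Returns
    (base_mean, log2fc, p, tested)."""
    ya = counts_a / sf_a
    yb = counts_b / sf_b
    na, nb = ya.shape[1], yb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per condition")
    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    base_mean = np.concatenate([ya, yb], axis=1).mean(axis=1)
    tested = base_mean > 0

    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    df_resid = na + nb - 2
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - base_mean) / base_mean**2
    disp = np.where(np.isfinite(disp), disp, 0.0)
    # moderate the noisy gene-wise moment estimate toward the across-gene
    # median (empirical-Bayes prior with DISPERSION_PRIOR_DF pseudo-df)
    disp_prior = float(np.median(disp[tested])) if tested.any() else 0.0
    d0 = DISPERSION_PRIOR_DF
    disp = (d0 * disp_prior + df_resid * disp) / (d0 + df_resid)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    c = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((mb + c) / (ma + c))

    inv_a = np.mean(1.0 / sf_a)
    inv_b = np.mean(1.0 / sf_b)
    var_ma = (ma * inv_a + disp * ma**2) / na
    var_mb = (mb * inv_b + disp * mb**2) / nb
    se = np.sqrt(var_ma / (ma + c) ** 2 + var_mb / (mb + c) ** 2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=d0 + df_resid)
    p = np.where(tested, p, 1.0)
    log2fc = np.where(tested, log2fc, 0.0)
    return base_mean, log2fc, p, tested


def nb_test_all(
    table: CountTable,
    cell_line: str,
    sf: np.ndarray | None = None,
    q_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Run the siMyb vs siNEG NB Wald test for every gene of one cell line.

    Size factors default to median-of-ratios on that cell line's samples.
    Returns a DataFrame with columns gene_id, base_mean, log2fc, p, q,
    call, tested.  Untested (all-zero) genes carry p = 1, log2fc = 0.
    """
    in_line = table.samples["cell_line"] == cell_line
    if not in_line.any():
        raise ValueError(f"no samples for cell line {cell_line!r}")
    sub = table.select_samples(in_line.to_numpy())
    if sf is None:
        sf = size_factors(sub)
    is_b = (sub.samples["treatment"] == "siMyb").to_numpy()
    counts = sub.matrix.astype(float)
    base_mean, log2fc, p, tested = _wald_nb(
        counts[:, ~is_b], counts[:, is_b], sf[~is_b], sf[is_b]
    )
    q = bh_adjust(p)
    call = np.where(
        (q < q_threshold) & (log2fc <= -min_abs_log2fc),
        "down",
        np.where((q < q_threshold) & (log2fc >= min_abs_log2fc), "up", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "call": call,
            "tested": tested,
        }
    )


def nb_test(
    table: CountTable, cell_line: str, gene_id: str
) -> tuple[float, float]:
    """(p_value, log2fc) for one gene; convenience wrapper over nb_test_all."""
    res = nb_test_all(table, cell_line)
    row = res[res["gene_id"] == gene_id]
    if row.empty:
        raise KeyError(gene_id)
    return float(row["p"].iloc[0]), float(row["log2fc"].iloc[0])


def call_de(
    results: pd.DataFrame,
    q_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> tuple[set[str], set[str]]:
    """(down, up) gene-id sets at the given q and |log2FC| thresholds."""
    if results.empty:
        return set(), set()
    sig = results["q"] < q_threshold
    down = set(results.loc[sig & (results["log2fc"] <= -min_abs_log2fc), "gene_id"])
    up = set(results.loc[sig & (results["log2fc"] >= min_abs_log2fc), "gene_id"])
    return down, up


# ---------------------------------------------------------------------------
# FPKM and clustering summaries
# ---------------------------------------------------------------------------


def fpkm(table: CountTable, gene_models: list[GeneModel]) -> pd.DataFrame:
    """FPKM matrix: count * 1e9 / (exonic_length * library size)."""
    lengths = {g.gene_id: g.exonic_length for g in gene_models}
    missing = [g for g in table.gene_ids if g not in lengths]
    if missing:
        raise ValueError(f"genes without models: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    length_vec = np.array([lengths[g] for g in table.gene_ids], dtype=float)
    libsize = table.matrix.sum(axis=0).astype(float)
    mat = table.matrix * 1e9 / (length_vec[:, None] * libsize[None, :])
    return pd.DataFrame(mat, index=table.gene_ids, columns=table.sample_ids)


def spearman_cluster(
    fpkm_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman correlation of samples on log2(FPKM+1) plus average-linkage
    dendrogram leaf order on distance 1 - rho."""
    if fpkm_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    logged = np.log2(fpkm_matrix.to_numpy() + 1.0)
    if (logged.std(axis=0) == 0).any():
        const = fpkm_matrix.columns[logged.std(axis=0) == 0]
        raise ValueError(f"constant samples have undefined rho: {list(const)}")
    rho = stats.spearmanr(logged).statistic
    rho = np.atleast_2d(rho)
    corr = pd.DataFrame(rho, index=fpkm_matrix.columns, columns=fpkm_matrix.columns)
    dist = squareform(1.0 - rho, checks=False)
    order = leaves_list(average(dist))
    return corr, [fpkm_matrix.columns[i] for i in order]


def cluster_log2fc(
    fc_matrix: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Average-linkage Euclidean clustering of cell-line columns of a
    log2 fold-change matrix; rows ordered by the first leaf column's values
    (descending), ties broken by gene id.  Returns (row_order, col_order)."""
    clean = fc_matrix.dropna()
    if clean.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    dist = pdist(clean.to_numpy().T, metric="euclidean")
    col_order = [clean.columns[i] for i in leaves_list(average(dist))]
    first = col_order[0]
    rows = clean[[first]].copy()
    rows["_gene"] = rows.index
    row_order = list(
        rows.sort_values([first, "_gene"], ascending=[False, True]).index
    )
    return row_order, col_order


def venn_overlaps(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Exact cardinalities of all 2^k - 1 exclusive Venn regions."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_overlaps supports 2 or 3 sets")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            members = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members -= sets[n]
            regions[frozenset(inside)] = len(members)
    return regions
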
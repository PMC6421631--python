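"""Join binding classes to expression responses.

Each classified peak is linked to the gene whose TSS is closest to its
merged summit; knockdown log2 fold changes of those genes are then laid
out along the p30/p42 ranking (the expression heat map) and summarised
per peak class and cell line, with pairwise Mann-Whitney comparisons
between classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .peak_classify import ClassifiedPeak

__all__ = [
    "PeakGeneLink",
    "nearest_gene",
    "ranked_expression_heatmap",
    "group_fold_change",
]


@dataclass(frozen=True)
class PeakGeneLink:
    """Signed distance is summit - TSS on the gene's strand: negative means
    the summit lies upstream of the TSS."""

    peak_id: str
    gene_id: str
    distance: int


def nearest_gene(
    peaks: list[ClassifiedPeak],
    gene_models: list[GeneModel],
    max_distance: int | None = None,
) -> list[PeakGeneLink]:
    """Link every peak to the gene minimising |summit - TSS|.

    Ties go to the lexicographically smaller gene_id; peaks on chromosomes
    without genes (or beyond ``max_distance``) are omitted.
    """
    if not gene_models:
        raise ValueError("no gene models")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in genes]), genes)
    links = []
    for p in peaks:
        entry = index.get(p.summit.chrom)
        if entry is None:
            continue
        tss, genes = entry
        pos = p.summit.summit_pos
        i = int(np.searchsorted(tss, pos))
        # candidates around the insertion point; widen by one on each side
        # so equal-|distance| ties are all seen
        cands = [
            genes[j] for j in range(max(0, i - 2), min(len(genes), i + 2))
        ]
        best = min(cands, key=lambda g: (abs(pos - g.tss), g.gene_id))
        dist = pos - best.tss if best.strand == "+" else best.tss - pos
        if max_distance is not None and abs(dist) > max_distance:
            continue
        links.append(PeakGeneLink(p.uid, best.gene_id, int(dist)))
    return links


def ranked_expression_heatmap(
    classified: list[ClassifiedPeak],
    links: list[PeakGeneLink],
    fc_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Per-peak knockdown log2FC matrix (peaks x cell lines) in rank order.

    Rows of peaks whose linked gene is absent from ``fc_matrix`` (or that
    have no link at all) are NaN.  An extra ``class`` column records the
    block structure of the ranking.
    """
    link_by_peak = {ln.peak_id: ln.gene_id for ln in links}
    ordered = sorted(classified, key=lambda p: p.rank)
    rows = []
    for p in ordered:
        gene = link_by_peak.get(p.uid)
        if gene is not None and gene in fc_matrix.index:
            vals = fc_matrix.loc[gene].to_dict()
        else:
            vals = {c: np.nan for c in fc_matrix.columns}
        rows.append({"peak_id": p.uid, "class": p.peak_class, **vals})
    return pd.DataFrame(rows).set_index("peak_id")


def group_fold_change(
    links: list[PeakGeneLink],
    classified: list[ClassifiedPeak],
    fc_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (peak class, cell line) fold-change summaries plus pairwise
    two-sided Mann-Whitney tests between classes.

    Genes linked by several peaks of one class are counted once; missing
    fold changes are dropped, not imputed.  Returns (summary, tests);
    classes with fewer than 2 genes appear in the summary but are skipped
    in the tests.
    """
    class_by_peak = {p.uid: p.peak_class for p in classified}
    genes_per_class: dict[str, set[str]] = {}
    for ln in links:
        cls = class_by_peak.get(ln.peak_id)
        if cls is not None:
            genes_per_class.setdefault(cls, set()).add(ln.gene_id)
    summary_rows = []
    values: dict[tuple[str, str], np.ndarray] = {}
    for cls, genes in sorted(genes_per_class.items()):
        present = sorted(g for g in genes if g in fc_matrix.index)
        for cell_line in fc_matrix.columns:
            v = fc_matrix.loc[present, cell_line].dropna().to_numpy()
            values[(cls, cell_line)] = v
            summary_rows.append(
                {
                    "class": cls,
                    "cell_line": cell_line,
                    "n_genes": len(v),
                    "mean_log2fc": float(np.mean(v)) if len(v) else np.nan,
                    "median_log2fc": float(np.median(v)) if len(v) else np.nan,
                    "q25": float(np.percentile(v, 25)) if len(v) else np.nan,
                    "q75": float(np.percentile(v, 75)) if len(v) else np.nan,
                }
            )
    test_rows = []
    for cell_line in fc_matrix.columns:
        for a, b in itertools.combinations(sorted(genes_per_class), 2):
            va, vb = values[(a, cell_line)], values[(b, cell_line)]
            if len(va) < 2 or len(vb) < 2:
                continue
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            test_rows.append(
                {
                    "cell_line": cell_line,
                    "class_a": a,
                    "class_b": b,
                    "u_statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)
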
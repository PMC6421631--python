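"""Gene-set enrichment statistics.

Three related computations:

* ``set_mean_log2fc`` — the average knockdown log2 fold change of a gene
  set, with a two-sided permutation p against random same-size draws from
  the universe (the bar-plot statistic for curated ontology classes).
* ``hypergeom_overrep`` — classic upper-tail hypergeometric
  over-representation of gene sets in a foreground list (GO analysis of
  peak-class genes).
* ``gsea_es`` / ``gsea_significance`` — the weighted Kolmogorov-Smirnov
  enrichment score over a fold-change-ranked gene list with a gene-label
  permutation null, normalised enrichment scores and BH-adjusted q-values
  (binding-vs-expression GSEA).  Gene-label permutation is used because
  the ranked list derives from a single contrast with three replicates a
  side, where sample permutation is not feasible.

Gene sets travel in GMT (tab-separated: set_id, description, members).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .integration import PeakGeneLink
from .peak_classify import ClassifiedPeak

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "set_mean_log2fc",
    "hypergeom_overrep",
    "gsea_es",
    "gsea_significance",
    "top_peak_gene_set",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    statistic: float  # mean log2fc, ES, or odds ratio
    p_value: float | None
    q_value: float | None = None
    direction: str = "none"  # up | down | none
    nes: float | None = None
    unstable: bool = False


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs >= 3 columns")
            sets.append(GeneSet(f[0], f[1], frozenset(x for x in f[2:] if x)))
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Mean fold change of a set, permutation null
# ---------------------------------------------------------------------------


def set_mean_log2fc(
    gene_set: GeneSet,
    fold_changes: pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Mean log2FC of the set members present in ``fold_changes``, with a
    two-sided permutation p-value ((b+1)/(n_perm+1)) against means of
    random same-size draws from the universe.  ``n_perm=0`` returns the
    statistic only (p is None)."""
    present = sorted(set(gene_set.members) & set(fold_changes.index))
    if not present:
        raise ValueError(f"no members of {gene_set.set_id} in the universe")
    values = fold_changes.to_numpy(dtype=float)
    obs = float(fold_changes.loc[present].mean())
    direction = "up" if obs > 0 else "down" if obs < 0 else "none"
    if n_perm == 0:
        return EnrichmentResult(gene_set.set_id, obs, None, direction=direction)
    rng = np.random.default_rng(seed)
    k = len(present)
    global_mean = float(values.mean())
    perm_means = np.empty(n_perm)
    for i in range(n_perm):
        perm_means[i] = values[rng.choice(len(values), size=k, replace=False)].mean()
    # epsilon guards against float noise when the set spans the universe
    obs_dev = abs(obs - global_mean)
    b = int(np.sum(np.abs(perm_means - global_mean) >= obs_dev - 1e-12))
    p = (b + 1) / (n_perm + 1)
    return EnrichmentResult(gene_set.set_id, obs, p, direction=direction)


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------


def hypergeom_overrep(
    foreground: set[str],
    background: set[str],
    gene_sets: list[GeneSet],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each set's overlap with the
    foreground, BH-adjusted across sets; odds ratio Haldane-corrected."""
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    M, n_fg = len(background), len(foreground)
    raw = []
    for gs in gene_sets:
        members = gs.members & background
        k = len(members & foreground)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_fg)) if K else 1.0
        a, b = k + 0.5, len(foreground - members) + 0.5
        c, d = K - k + 0.5, M - n_fg - (K - k) + 0.5
        raw.append((gs.set_id, (a * d) / (b * c), min(p, 1.0)))
    q = bh_adjust([r[2] for r in raw])
    return [
        EnrichmentResult(sid, oratio, p, q_value=float(qv),
                         direction="up" if oratio > 1 else "down")
        for (sid, oratio, p), qv in zip(raw, q)
    ]


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _running_sum(
    scores: np.ndarray, hits: np.ndarray, weight: float
) -> np.ndarray:
    """Weighted KS running sum over a ranked list; ``hits`` is boolean."""
    n = len(scores)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == n:
        # degenerate: no misses to step down on
        w = np.abs(scores) ** weight
        denom = w.sum()
        if denom == 0:
            raise ValueError("all scores are zero with positive weight")
        return np.cumsum(w / denom)
    w = np.where(hits, np.abs(scores) ** weight, 0.0)
    denom = w.sum()
    if denom == 0:
        raise ValueError("all hit scores are zero with positive weight")
    steps = np.where(hits, w / denom, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def gsea_es(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: GeneSet,
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score of ``gene_set`` on a ranked gene list.

    ``ranked_genes`` must be unique and sorted by decreasing ``scores``;
    the ES is the extremum (sign retained) of the running sum where set
    members step up by |score|^weight (normalised) and non-members step
    down by 1/(N - n_hits)."""
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranked gene ids must be unique")
    scores = np.asarray(scores, dtype=float)
    hits = np.fromiter(
        (g in gene_set.members for g in ranked_genes), dtype=bool,
        count=len(ranked_genes),
    )
    running = _running_sum(scores, hits, weight)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_significance(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_sets: list[GeneSet] | GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-label permutation significance for one or more gene sets.

    The null preserves each set's in-list size and redraws membership
    uniformly over ranked positions.  NES = ES / mean(|null ES| of the
    matching sign); p = (b+1)/(n_same+1) over same-sign null scores, and
    a set with no same-sign null ES gets p = 1/(n_perm+1) and is flagged
    unstable.  q is BH across the tested sets.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    scores = np.asarray(scores, dtype=float)
    n = len(ranked_genes)
    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for gs in gene_sets:
        es, _ = gsea_es(ranked_genes, scores, gs, weight)
        k = sum(g in gs.members for g in ranked_genes)
        if k not in null_cache:
            null_es = np.empty(n_perm)
            for i in range(n_perm):
                hits = np.zeros(n, dtype=bool)
                hits[rng.choice(n, size=k, replace=False)] = True
                running = _running_sum(scores, hits, weight)
                j = int(np.argmax(np.abs(running)))
                null_es[i] = running[j]
            null_cache[k] = null_es
        null_es = null_cache[k]
        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
            unstable = True
        else:
            b = int(np.sum(np.abs(same) >= abs(es)))
            p = (b + 1) / (len(same) + 1)
            nes = es / np.mean(np.abs(same))
            unstable = False
        rows.append(
            {
                "set_id": gs.set_id,
                "es": es,
                "nes": nes,
                "p": p,
                "unstable": unstable,
                "direction": "up" if es > 0 else "down",
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def top_peak_gene_set(
    classified: list[ClassifiedPeak],
    links: list[PeakGeneLink],
    factor: str,
    n_top: int = 1000,
    set_id: str | None = None,
) -> GeneSet:
    """Gene set of the nearest genes of the top-``n_top`` peaks of one
    factor, ranked by its normalised tag count at merged summits and
    deduplicated by gene."""
    gene_by_peak = {ln.peak_id: ln.gene_id for ln in links}
    ordered = sorted(
        classified, key=lambda p: (-p.counts[factor], p.summit.chrom, p.summit.summit_pos)
    )
    genes = []
    seen: set[str] = set()
    for p in ordered[:n_top]:
        g = gene_by_peak.get(p.uid)
        if g is not None and g not in seen:
            seen.add(g)
            genes.append(g)
    sid = set_id or f"top{n_top}_{factor}_peak_genes"
    return GeneSet(sid, sid, frozenset(genes))
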
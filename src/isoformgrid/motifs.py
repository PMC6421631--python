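"""Known-motif scanning and differential motif enrichment between peak classes.

PWMs are scored as log2 odds against the background on both strands of a
summit-centred sequence window; a position is a hit when its score reaches
a fixed fraction of the motif's maximum attainable score (a deterministic,
background-model-free threshold).  Per-peak hit indicators then feed a
one-sided Fisher exact test between two peak classes and a binary
match matrix along the p30/p42 ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import BASES, PWMRecord
from .peak_classify import ClassifiedPeak

__all__ = [
    "MotifHit",
    "MotifEnrichment",
    "scan_pwm",
    "scan_peaks",
    "peak_window_sequences",
    "class_motif_enrichment",
    "motif_match_matrix",
]

_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    peak_id: str
    offset: int  # window start of the match within the scanned sequence
    strand: str
    score: float  # log2 odds (bits)


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    n_hit_a: int
    n_a: int
    n_hit_b: int
    n_b: int
    odds_ratio: float
    p_value: float
    q_value: float
    neg_log10_p: float
    rank: int


def _logodds(pwm: PWMRecord) -> np.ndarray:
    """positions x 5 log2-odds matrix; column 4 (N) is -inf."""
    lo = np.log2(pwm.matrix / pwm.background[None, :])
    return np.hstack([lo, np.full((len(pwm), 1), -np.inf)])


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_CODE[b] for b in sequence.upper()), dtype=np.int8,
            count=len(sequence),
        )
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from None


def scan_pwm(
    sequence: str,
    pwm: PWMRecord,
    threshold_fraction: float = 0.8,
    peak_id: str = ".",
) -> list[MotifHit]:
    """Scan both strands of ``sequence``; a hit scores at least
    ``threshold_fraction`` times the maximum attainable score.  Positions
    containing N cannot contribute (they score -inf).  A PWM longer than
    the sequence yields no hits."""
    L = len(pwm)
    if L > len(sequence):
        return []
    codes = _encode(sequence)
    lo = _logodds(pwm)
    lo_rc = lo[::-1, [3, 2, 1, 0, 4]]  # reverse-complement strand
    max_score = float(lo[:, :4].max(axis=1).sum())
    cutoff = threshold_fraction * max_score
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    idx = np.arange(L)
    hits = []
    for strand, mat in (("+", lo), ("-", lo_rc)):
        with np.errstate(invalid="ignore"):
            scores = mat[idx[None, :], windows].sum(axis=1)
        for off in np.nonzero(scores >= cutoff)[0]:
            hits.append(
                MotifHit(pwm.motif_id, peak_id, int(off), strand, float(scores[off]))
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def peak_window_sequences(
    genome: dict[str, str],
    classified: list[ClassifiedPeak],
    half_width: int = 100,
) -> dict[str, str]:
    """Summit-centred sequence windows (clipped at chromosome ends)."""
    out = {}
    for p in classified:
        seq = genome.get(p.summit.chrom)
        if seq is None:
            raise KeyError(f"chromosome {p.summit.chrom} not in genome")
        lo = max(0, p.summit.summit_pos - half_width)
        hi = min(len(seq), p.summit.summit_pos + half_width)
        out[p.uid] = seq[lo:hi]
    return out


def scan_peaks(
    sequences: dict[str, str],
    pwms: list[PWMRecord],
    threshold_fraction: float = 0.8,
) -> list[MotifHit]:
    hits = []
    for peak_id in sequences:
        for pwm in pwms:
            hits.extend(
                scan_pwm(sequences[peak_id], pwm, threshold_fraction, peak_id)
            )
    return hits


def class_motif_enrichment(
    hits: list[MotifHit],
    classified: list[ClassifiedPeak],
    class_a: str,
    class_b: str,
) -> list[MotifEnrichment]:
    """One-sided Fisher exact enrichment of each motif's hit peaks in
    ``class_a`` versus ``class_b``; BH across motifs, ranked by
    descending -log10 p."""
    peaks_a = {p.uid for p in classified if p.peak_class == class_a}
    peaks_b = {p.uid for p in classified if p.peak_class == class_b}
    if not peaks_a or not peaks_b:
        raise ValueError("both classes must contain peaks")
    motif_ids = sorted({h.motif_id for h in hits})
    hit_peaks: dict[str, set[str]] = {m: set() for m in motif_ids}
    for h in hits:
        hit_peaks[h.motif_id].add(h.peak_id)
    rows = []
    for m in motif_ids:
        a_hit = len(hit_peaks[m] & peaks_a)
        b_hit = len(hit_peaks[m] & peaks_b)
        table = [
            [a_hit, len(peaks_a) - a_hit],
            [b_hit, len(peaks_b) - b_hit],
        ]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        oratio = ((a_hit + 0.5) * (len(peaks_b) - b_hit + 0.5)) / (
            (len(peaks_a) - a_hit + 0.5) * (b_hit + 0.5)
        )
        rows.append((m, a_hit, b_hit, oratio, p))
    q = bh_adjust([r[4] for r in rows])
    order = sorted(
        range(len(rows)), key=lambda i: (-(-np.log10(rows[i][4])), rows[i][0])
    )
    rank_of = {i: r + 1 for r, i in enumerate(order)}
    return [
        MotifEnrichment(
            motif_id=m,
            n_hit_a=a_hit,
            n_a=len(peaks_a),
            n_hit_b=b_hit,
            n_b=len(peaks_b),
            odds_ratio=oratio,
            p_value=p,
            q_value=float(qv),
            neg_log10_p=float(-np.log10(p)),
            rank=rank_of[i],
        )
        for i, ((m, a_hit, b_hit, oratio, p), qv) in enumerate(zip(rows, q))
    ]


def motif_match_matrix(
    hits: list[MotifHit],
    classified: list[ClassifiedPeak],
    motif_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Binary peaks x motifs matrix in classification rank order, with a
    ``class`` column recording block boundaries."""
    if motif_ids is None:
        motif_ids = sorted({h.motif_id for h in hits})
    hit_pairs = {(h.peak_id, h.motif_id) for h in hits}
    ordered = sorted(classified, key=lambda p: p.rank)
    data = {
        m: [int((p.uid, m) in hit_pairs) for p in ordered] for m in motif_ids
    }
    out = pd.DataFrame(data, index=[p.uid for p in ordered])
    out.insert(0, "class", [p.peak_class for p in ordered])
    out.index.name = "peak_id"
    return out
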
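"""Self-contained synthetic dataset emulating an isoform ChIP-seq +
knockdown RNA-seq study, with machine-readable ground truth.

The generator lays out a single random chromosome with non-overlapping
genes, plants three classes of transcription-factor binding sites near a
subset of TSSs (p42-specific / shared / p30-specific, with distinct
expected p42:p30 tag rates), draws Poisson ChIP tags for five factors
(p42, p30, a DNA-binding-dead K313KK analogue, Myb and p300 — the last
three tied to the p42 signal, modelling the observed co-localisation),
plants consensus motif occurrences concentrated in one class each, and
simulates negative-binomial RNA-seq counts for three cell lines x
{siNEG, siMyb} in which knockdown response direction is linked to peak
class: genes near p42-specific sites are de-repressed (up) under
knockdown, genes near p30-specific sites go down, and the third cell
line barely responds at all.

Every output is deterministic given the master seed: each stage draws
from its own named substream, so adding an output never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    GeneModel,
    GenomicInterval,
    PeakRecord,
    TagTrack,
    write_bed12,
    write_counts,
    write_fasta,
    write_jaspar,
    write_narrowpeak,
    write_table,
    write_tags_bed,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_genome",
           "simulate_chip_tags", "simulate_rnaseq_counts", "simulate_all"]

CLASSES = ("p42_specific", "shared", "p30_specific")
FACTORS = ("p42", "p30", "k313kk", "myb", "p300")
CELL_LINES = ("FMH9", "KL", "LL")  # wild-type-like, double-mutant, N-term-only


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults define the reference fixture."""

    seed: int = 1
    chrom: str = "chr1"
    genome_length: int = 2_000_000
    n_genes: int = 1000
    # peaks per class; each peak is a fixed-width window, summit centred,
    # placed near the TSS of a distinct gene so nearest-gene links are
    # unambiguous by construction
    n_peaks: dict[str, int] = field(
        default_factory=lambda: {"p42_specific": 150, "shared": 400,
                                 "p30_specific": 150}
    )
    peak_width: int = 400
    summit_jitter: int = 250  # max |summit - TSS| of the host gene
    # mean in-window tag counts (Poisson) for (p42, p30) per class
    class_tag_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "p42_specific": (80.0, 10.0),
            "shared": (60.0, 60.0),
            "p30_specific": (10.0, 80.0),
        }
    )
    myb_rate_factor: float = 0.8   # Myb tracks the p42 signal
    p300_rate_factor: float = 0.5  # ditto, weaker
    background_rate: float = 0.01  # background tags per bp per track
    k313kk_total_tags: int = 50_000
    k313kk_in_peak_fraction: float = 0.1
    tag_spread_sd: float = 60.0  # sd (bp) of tag positions around summits
    # RNA-seq
    replicates: int = 3
    nb_dispersion: float = 0.05
    base_mean_log_mean: float = float(np.log(100.0))
    base_mean_log_sd: float = 1.2
    size_factor_range: tuple[float, float] = (0.8, 1.2)
    de_effect_log2fc: float = 2.0
    # probability that a peak-linked gene responds to knockdown, per class,
    # split into both-responsive-lines vs a single line; direction is +1
    # (up under siMyb) for p42-linked, -1 for p30-linked, mixed for shared
    p_respond_both: dict[str, float] = field(
        default_factory=lambda: {"p42_specific": 0.35, "shared": 0.1,
                                 "p30_specific": 0.35}
    )
    p_respond_single: dict[str, float] = field(
        default_factory=lambda: {"p42_specific": 0.15, "shared": 0.05,
                                 "p30_specific": 0.15}
    )
    n_de_null_line: int = 10       # token responders in the LL analogue
    n_baseline_shift: int = 300    # genes 2x higher at baseline in KL and LL
    baseline_shift_log2: float = 1.0
    n_line_markers: int = 100      # line-identity genes shifted in one line
    line_marker_log2: float = 1.0
    # motif planting: class -> {motif_id: plant probability}
    motif_consensus: dict[str, str] = field(
        default_factory=lambda: {"CEBP_like": "ATTGCGCAAT",
                                 "CTCF_like": "CCACCAGGGGGC"}
    )
    motif_plant_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "p42_specific": {"CEBP_like": 0.9},
            "shared": {"CEBP_like": 0.5},
            "p30_specific": {"CTCF_like": 0.9},
        }
    )

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.k313kk_in_peak_fraction <= 1:
            raise ValueError("k313kk_in_peak_fraction must be in [0, 1]")
        if self.background_rate < 0 or any(
            r < 0 for pair in self.class_tag_rates.values() for r in pair
        ):
            raise ValueError("tag rates must be >= 0")
        if any(n < 1 for n in self.n_peaks.values()):
            raise ValueError("each peak class needs >= 1 peak")

    @property
    def n_peaks_total(self) -> int:
        return sum(self.n_peaks.values())

    def factor_rate(self, factor: str, peak_class: str) -> float:
        """Expected in-window tag count of ``factor`` at a peak of class."""
        p42, p30 = self.class_tag_rates[peak_class]
        return {
            "p42": p42,
            "p30": p30,
            "myb": self.myb_rate_factor * p42,
            "p300": self.p300_rate_factor * p42,
        }[factor]

    def expected_in_peak_fraction(self) -> dict[str, float]:
        bg = self.background_rate * self.genome_length
        out = {}
        for f in ("p42", "p30", "myb", "p300"):
            in_peak = sum(
                self.n_peaks[c] * self.factor_rate(f, c) for c in CLASSES
            )
            cover = self.n_peaks_total * self.peak_width / self.genome_length
            out[f] = (in_peak + bg * cover) / (in_peak + bg)
        out["k313kk"] = self.k313kk_in_peak_fraction
        return out


@dataclass
class GroundTruth:
    """Planted truth: per-peak classes/links/motifs and per-gene DE labels."""

    peaks: pd.DataFrame  # peak_id, chrom, summit, class, gene_id, motifs
    genes: pd.DataFrame  # gene_id, tss, strand, linked_peak, baseline_shift,
    #                      de_<line>, log2fc_<line>
    in_peak_fraction: dict[str, float]

    def expected_group_mean(self, peak_class: str, cell_line: str) -> float:
        """Config-implied mean knockdown log2FC of genes linked to a class."""
        linked = self.peaks.loc[self.peaks["class"] == peak_class, "gene_id"]
        fc = self.genes.set_index("gene_id").loc[linked, f"log2fc_{cell_line}"]
        return float(fc.mean())

    def to_frame(self) -> pd.DataFrame:
        p = self.peaks.copy()
        p.insert(0, "table", "peak")
        g = self.genes.copy()
        g.insert(0, "table", "gene")
        return pd.concat([p, g], ignore_index=True)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, in_peak_fraction: dict[str, float] | None = None
    ) -> "GroundTruth":
        peaks = (
            df[df["table"] == "peak"].dropna(axis=1, how="all").drop(columns="table")
        )
        genes = (
            df[df["table"] == "gene"].dropna(axis=1, how="all").drop(columns="table")
        )
        return cls(peaks.reset_index(drop=True), genes.reset_index(drop=True),
                   in_peak_fraction or {})


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Named substream: independent of every other tag, stable across runs."""
    digest = hashlib.sha256(tag.encode()).digest()
    return np.random.default_rng(
        [seed % 2**31, int.from_bytes(digest[:4], "big") % 2**31]
    )


# ---------------------------------------------------------------------------
# Genome, genes, peak layout, motif planting
# ---------------------------------------------------------------------------


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Random genome + non-overlapping gene models + planted peak truth.

    Genes occupy fixed slots with generous margins so that adjacent TSSs
    are far enough apart for summit merging and nearest-gene assignment
    to be unambiguous for planted peaks.
    """
    slot = config.genome_length // config.n_genes
    margin = 450
    max_gene_len = 1000
    min_gene_len = 600
    if slot < max_gene_len + 2 * margin:
        raise ValueError(
            f"cannot place {config.n_genes} non-overlapping genes on a "
            f"{config.genome_length} bp genome; increase genome_length"
        )
    rng = _rng(config.seed, "genome")
    seq = rng.integers(0, 4, size=config.genome_length, dtype=np.int8)

    models: list[GeneModel] = []
    tss_list, strands = [], []
    lengths = rng.integers(min_gene_len, max_gene_len + 1, size=config.n_genes)
    offsets = np.array(
        [rng.integers(margin, slot - margin - L + 1) for L in lengths]
    )
    gene_strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    for i in range(config.n_genes):
        start = i * slot + int(offsets[i])
        end = start + int(lengths[i])
        strand = str(gene_strands[i])
        # two exons separated by one intron (~20% of the span)
        e1 = int(0.4 * lengths[i])
        intron = int(0.2 * lengths[i])
        exons = ((start, start + e1), (start + e1 + intron, end))
        gene_id = f"gene_{i:04d}"
        models.append(
            GeneModel(
                gene_id=gene_id,
                symbol=gene_id,
                interval=GenomicInterval(config.chrom, start, end, strand),
                strand=strand,
                exonic_length=sum(b - a for a, b in exons),
                exons=exons,
            )
        )
        tss_list.append(models[-1].tss)
        strands.append(strand)

    # assign peaks to distinct host genes
    rng_peaks = _rng(config.seed, "peak_layout")
    host_idx = rng_peaks.choice(
        config.n_genes, size=config.n_peaks_total, replace=False
    )
    host_idx.sort()
    class_labels = np.concatenate(
        [np.full(config.n_peaks[c], c) for c in CLASSES]
    )
    rng_peaks.shuffle(class_labels)
    half = config.peak_width // 2
    peak_rows = []
    for j, (gi, cls) in enumerate(zip(host_idx, class_labels)):
        summit = tss_list[gi] + int(
            rng_peaks.integers(-config.summit_jitter, config.summit_jitter + 1)
        )
        summit = int(np.clip(summit, half, config.genome_length - half - 1))
        planted = []
        for motif_id, rate in config.motif_plant_rate.get(cls, {}).items():
            if rng_peaks.random() < rate:
                consensus = config.motif_consensus[motif_id]
                codes = np.array(
                    ["ACGT".index(b) for b in consensus], dtype=np.int8
                )
                if rng_peaks.random() < 0.5:  # plant on the minus strand
                    codes = (3 - codes)[::-1]
                lo = summit - 100
                pos = lo + int(rng_peaks.integers(0, 200 - len(codes) + 1))
                seq[pos : pos + len(codes)] = codes
                planted.append(motif_id)
        peak_rows.append(
            {
                "peak_id": f"peak_{j:04d}",
                "chrom": config.chrom,
                "summit": summit,
                "class": cls,
                "gene_id": f"gene_{gi:04d}",
                "motifs": ",".join(planted),
            }
        )
    peaks_df = pd.DataFrame(peak_rows)

    genes_df = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "tss": tss_list,
            "strand": strands,
        }
    )
    link = peaks_df.set_index("gene_id")["peak_id"]
    genes_df["linked_peak"] = genes_df["gene_id"].map(link).fillna("")
    genome = {
        config.chrom: "".join(np.array(list("ACGT"))[seq])
    }
    truth = GroundTruth(
        peaks=peaks_df, genes=genes_df,
        in_peak_fraction=config.expected_in_peak_fraction(),
    )
    return genome, models, truth


# ---------------------------------------------------------------------------
# ChIP tags
# ---------------------------------------------------------------------------


def _in_window_positions(
    rng: np.random.Generator, summit: int, n: int, sd: float, half: int
) -> np.ndarray:
    pos = np.rint(rng.normal(summit, sd, size=n)).astype(np.int64)
    return np.clip(pos, summit - half, summit + half - 1)


def simulate_chip_tags(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, TagTrack], dict[str, list[PeakRecord]]]:
    """Poisson tag tracks and narrowPeak calls for the five factors.

    p42/p30 rates come from the class definition; Myb and p300 follow
    the p42 rate of each peak.  The K313KK analogue draws a fixed total
    with ``k313kk_in_peak_fraction`` of tags inside peak windows and the
    rest strictly outside, and its peak list covers every window (the
    inflated, non-specific call set).  Everything else gets genome-wide
    uniform background on top of in-peak signal.
    """
    half = config.peak_width // 2
    summits = truth.peaks["summit"].to_numpy()
    classes = truth.peaks["class"].to_numpy()
    n_peaks = len(summits)

    tracks: dict[str, TagTrack] = {}
    calls: dict[str, list[PeakRecord]] = {}

    def window_peak_records(mask: np.ndarray) -> list[PeakRecord]:
        recs = []
        for i in np.nonzero(mask)[0]:
            recs.append(
                PeakRecord(
                    GenomicInterval(
                        config.chrom, int(summits[i] - half),
                        int(summits[i] + half)
                    ),
                    summit_offset=half,
                    name=str(truth.peaks["peak_id"].iloc[i]),
                )
            )
        return recs

    for factor in ("p42", "p30", "myb", "p300"):
        rng = _rng(config.seed, f"tags_{factor}")
        rates = np.array([config.factor_rate(factor, c) for c in classes])
        counts = rng.poisson(rates)
        pos_chunks = [
            _in_window_positions(rng, s, n, config.tag_spread_sd, half)
            for s, n in zip(summits, counts)
            if n > 0
        ]
        n_bg = rng.poisson(config.background_rate * config.genome_length)
        pos_chunks.append(
            rng.integers(0, config.genome_length, size=n_bg, dtype=np.int64)
        )
        all_pos = np.concatenate(pos_chunks)
        if len(all_pos) == 0:
            raise ValueError(f"zero total tags for factor {factor}")
        tracks[factor] = TagTrack(factor, {config.chrom: all_pos})
        involved = (
            np.isin(classes, ["p42_specific", "shared"])
            if factor != "p30"
            else np.isin(classes, ["shared", "p30_specific"])
        )
        calls[factor] = window_peak_records(involved)

    # K313KK: background-dominated, fixed in-peak fraction, inflated calls
    rng = _rng(config.seed, "tags_k313kk")
    total = config.k313kk_total_tags
    if total == 0:
        raise ValueError("zero total tags for factor k313kk")
    n_in = rng.binomial(total, config.k313kk_in_peak_fraction)
    per_peak = rng.multinomial(n_in, np.full(n_peaks, 1.0 / n_peaks))
    pos_chunks = [
        _in_window_positions(rng, s, n, config.tag_spread_sd, half)
        for s, n in zip(summits, per_peak)
        if n > 0
    ]
    # complement of the peak windows, sampled uniformly by length
    gaps = []
    prev = 0
    for lo, hi in sorted(zip(summits - half, summits + half)):
        if lo > prev:
            gaps.append((prev, lo))
        prev = max(prev, hi)
    if prev < config.genome_length:
        gaps.append((prev, config.genome_length))
    gap_arr = np.array(gaps)
    gap_lens = gap_arr[:, 1] - gap_arr[:, 0]
    n_out = total - n_in
    which = rng.choice(len(gaps), size=n_out, p=gap_lens / gap_lens.sum())
    offs = rng.random(n_out) * gap_lens[which]
    pos_chunks.append((gap_arr[which, 0] + offs).astype(np.int64))
    tracks["k313kk"] = TagTrack("k313kk", {config.chrom: np.concatenate(pos_chunks)})
    calls["k313kk"] = window_peak_records(np.full(n_peaks, True))
    return tracks, calls


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

_CLASS_DIRECTION = {"p42_specific": 1.0, "p30_specific": -1.0}


def simulate_rnaseq_counts(
    config: SimulationConfig, truth: GroundTruth
) -> CountTable:
    """NB counts for three cell lines x {siNEG, siMyb} x replicates.

    Fills the per-gene DE columns of ``truth.genes`` in place: for each
    peak-linked gene a single draw decides whether it responds in both
    responsive lines (FMH9 and KL analogues), in exactly one, or not at
    all; response direction follows the host peak's class (+ for
    p42-specific, - for p30-specific, random for shared).  The third
    line (LL analogue) gets only ``n_de_null_line`` token responders.
    KL and LL share a planted 2x baseline shift on a subset of genes so
    steady-state expression clusters the two mutant analogues together.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = _rng(config.seed, "rnaseq")
    genes = truth.genes
    n = len(genes)
    base_mean = rng.lognormal(
        config.base_mean_log_mean, config.base_mean_log_sd, size=n
    )

    shift_idx = rng.choice(n, size=config.n_baseline_shift, replace=False)
    baseline = np.zeros(n)
    baseline[shift_idx] = config.baseline_shift_log2
    genes["baseline_shift"] = baseline

    # disjoint line-identity marker programmes (cell lines are distinct
    # entities, not replicates of one expression state)
    marker_pool = rng.permutation(np.setdiff1d(np.arange(n), shift_idx))
    markers: dict[str, np.ndarray] = {}
    marker_col = np.full(n, "", dtype=object)
    for i, line in enumerate(CELL_LINES):
        idx = marker_pool[i * config.n_line_markers:(i + 1) * config.n_line_markers]
        markers[line] = idx
        marker_col[idx] = line
    genes["marker_line"] = marker_col

    peak_class = truth.peaks.set_index("gene_id")["class"]
    log2fc = {line: np.zeros(n) for line in CELL_LINES}
    for i, gid in enumerate(genes["gene_id"]):
        cls = peak_class.get(gid)
        if cls is None:
            continue
        direction = _CLASS_DIRECTION.get(cls)
        if direction is None:  # shared peaks: random direction
            direction = 1.0 if rng.random() < 0.5 else -1.0
        u = rng.random()
        p_both = config.p_respond_both[cls]
        p_single = config.p_respond_single[cls]
        effect = direction * config.de_effect_log2fc
        if u < p_both:
            log2fc["FMH9"][i] = effect
            log2fc["KL"][i] = effect
        elif u < p_both + p_single:
            log2fc["FMH9"][i] = effect
        elif u < p_both + 2 * p_single:
            log2fc["KL"][i] = effect
    unlinked = np.nonzero((genes["linked_peak"] == "").to_numpy())[0]
    null_idx = rng.choice(unlinked, size=config.n_de_null_line, replace=False)
    signs = np.where(rng.random(config.n_de_null_line) < 0.5, 1.0, -1.0)
    log2fc["LL"][null_idx] = signs * config.de_effect_log2fc
    for line in CELL_LINES:
        genes[f"log2fc_{line}"] = log2fc[line]
        genes[f"de_{line}"] = np.where(
            log2fc[line] > 0, "up", np.where(log2fc[line] < 0, "down", "ns")
        )

    samples, columns = [], []
    lo, hi = config.size_factor_range
    for line in CELL_LINES:
        for treat in ("siNEG", "siMyb"):
            for rep in range(1, config.replicates + 1):
                sf = rng.uniform(lo, hi)
                mu = base_mean.copy()
                if line in ("KL", "LL"):
                    mu = mu * 2.0**baseline
                boost = np.zeros(n)
                boost[markers[line]] = config.line_marker_log2
                mu = mu * 2.0**boost
                if treat == "siMyb":
                    mu = mu * 2.0 ** log2fc[line]
                mu = mu * sf
                r_nb = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
                columns.append(counts)
                samples.append(
                    {
                        "sample_id": f"{line}_{treat}_r{rep}",
                        "cell_line": line,
                        "treatment": treat,
                        "replicate": rep,
                    }
                )
    return CountTable(
        gene_ids=list(genes["gene_id"]),
        samples=pd.DataFrame(samples),
        matrix=np.stack(columns, axis=1),
    )


# ---------------------------------------------------------------------------
# Everything
# ---------------------------------------------------------------------------


def synthetic_gene_sets(
    config: SimulationConfig, truth: GroundTruth, size: int = 50
) -> list:
    """Ontology-style gene sets with planted expression shifts.

    One set per (responsive line, direction) sampled from the planted
    responders — these carry a real mean fold-change shift — plus one
    random set from the whole gene universe as a null control.
    """
    from .enrichment import GeneSet

    rng = _rng(config.seed, "gene_sets")
    genes = truth.genes
    sets = []
    for line in ("FMH9", "KL"):
        for direction in ("up", "down"):
            pool = genes.loc[genes[f"de_{line}"] == direction, "gene_id"].to_numpy()
            n = min(size, len(pool))
            members = rng.choice(pool, size=n, replace=False)
            sid = f"planted_{direction}_{line}"
            sets.append(GeneSet(sid, sid, frozenset(members)))
    null = rng.choice(genes["gene_id"].to_numpy(), size=size, replace=False)
    sets.append(GeneSet("null_random", "null_random", frozenset(null)))
    return sets


def motif_count_matrices(config: SimulationConfig) -> dict[str, np.ndarray]:
    """JASPAR-style count matrices for the planted consensus motifs: 9
    observations of the consensus base, 0 elsewhere."""
    out = {}
    for motif_id, consensus in config.motif_consensus.items():
        counts = np.zeros((len(consensus), 4), dtype=int)
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = 9
        out[motif_id] = counts
    return out


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full fixture directory; returns the manifest dict.

    Files: genome.fa, genes.bed12, tags_<factor>.bed and
    peaks_<factor>.narrowPeak for the five factors, counts.tsv,
    samples.tsv, motifs.jaspar, ground_truth.tsv, manifest.json
    (17 files).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models, truth = simulate_genome(config)
    tracks, calls = simulate_chip_tags(config, truth)
    table = simulate_rnaseq_counts(config, truth)

    write_fasta(genome, outdir / "genome.fa")
    write_bed12(models, outdir / "genes.bed12")
    for factor in FACTORS:
        write_tags_bed(tracks[factor], outdir / f"tags_{factor}.bed")
        write_narrowpeak(calls[factor], outdir / f"peaks_{factor}.narrowPeak")
    write_counts(table, outdir / "counts.tsv", outdir / "samples.tsv")
    write_jaspar(motif_count_matrices(config), outdir / "motifs.jaspar")
    write_table(truth.to_frame(), outdir / "ground_truth.tsv")
    manifest = {
        "config": dataclasses.asdict(config),
        "expected_in_peak_fraction": truth.in_peak_fraction,
        "files": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ) + ["manifest.json"],
        "n_peaks": int(len(truth.peaks)),
        "n_genes": int(len(truth.genes)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
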
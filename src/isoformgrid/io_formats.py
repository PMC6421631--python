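"""Readers and writers for the genomic file formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open (`[start, end)`),
regardless of the on-disk dialect: BED-family inputs are already in that
convention, GTF (1-based, inclusive) is converted at the boundary.  Tag
positions are single base-pair 5' ends.  All tabular output is plain TSV
with a header row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "GeneModel",
    "TagTrack",
    "CountTable",
    "PWMRecord",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_models",
    "write_bed12",
    "read_tags_bed",
    "write_tags_bed",
    "read_jaspar",
    "write_jaspar",
    "read_counts",
    "write_counts",
    "write_table",
    "read_fasta",
    "write_fasta",
    "merge_intervals",
]

BASES = "ACGT"


class FormatError(ValueError):
    """A file violated its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakRecord:
    """A called ChIP-seq peak; ``summit_offset`` is relative to ``start``
    (-1 when the caller did not report a summit)."""

    interval: GenomicInterval
    summit_offset: int = -1
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position (interval midpoint when unknown)."""
        if self.summit_offset == -1:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """Gene with a strand-aware TSS and a base-wise-union exonic length.

    ``exons`` (half-open, merged, sorted) are retained when the source
    annotation provides them; they drive exonic/intronic region labels.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str
    exonic_length: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.exonic_length <= 0:
            raise ValueError(f"gene {self.gene_id}: exonic_length must be > 0")
        if self.exonic_length > len(self.interval):
            raise ValueError(
                f"gene {self.gene_id}: exonic_length {self.exonic_length} exceeds "
                f"gene span {len(self.interval)}"
            )

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


class TagTrack:
    """Per-factor ChIP tag 5' positions, sorted per chromosome.

    Parameters
    ----------
    factor_name : name of the immunoprecipitated factor.
    positions : mapping chromosome -> array of 0-based tag 5' positions.
    """

    def __init__(self, factor_name: str, positions: dict[str, np.ndarray]):
        self.factor_name = factor_name
        self.positions = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in positions.items()
        }
        self.total_tags = int(sum(len(p) for p in self.positions.values()))
        if self.total_tags == 0:
            raise ValueError(f"tag track {factor_name!r} is empty")

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Raw tag count with 5' position in ``[start, end)``."""
        pos = self.chrom_positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass
class CountTable:
    """Gene-level RNA-seq counts plus the sample sheet describing columns."""

    gene_ids: list[str]
    samples: pd.DataFrame  # columns: sample_id, cell_line, treatment, replicate
    matrix: np.ndarray  # genes x samples, non-negative integers

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if (self.matrix < 0).any():
            raise ValueError("negative counts are not allowed")
        bad = self.samples.loc[
            ~self.samples["treatment"].isin(["siNEG", "siMyb"]), "sample_id"
        ]
        if len(bad):
            raise ValueError(f"unknown treatment for samples: {list(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)

    def select_samples(self, mask: Sequence[bool]) -> "CountTable":
        mask = np.asarray(mask, dtype=bool)
        return CountTable(
            self.gene_ids,
            self.samples.loc[mask].reset_index(drop=True),
            self.matrix[:, mask],
        )


@dataclass(frozen=True)
class PWMRecord:
    """Position probability matrix over (A, C, G, T) with background."""

    motif_id: str
    matrix: np.ndarray  # positions x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be positions x 4")
        if ((m < 0) | (m > 1)).any():
            raise ValueError(f"PWM {self.motif_id}: probabilities outside [0,1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# narrowPeak / BED6
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (or BED6) file.

    Column 10, when present, is the summit offset from the peak start;
    BED6 input yields ``summit_offset = -1``.
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if not 6 <= len(fields) <= 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 6-10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4]) if fields[4] != "." else 0.0
                strand = fields[5]
                summit = int(fields[9]) if len(fields) == 10 else -1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                records.append(
                    PeakRecord(interval, summit_offset=summit, score=score, name=name)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_narrowpeak(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t"
                f"{p.score:g}\t{iv.strand}\t0\t-1\t-1\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# Gene models: GTF / BED12
# ---------------------------------------------------------------------------


def _merge_blocks(blocks: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Base-wise union of half-open blocks."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(blocks):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


merge_intervals = _merge_blocks


def _read_gtf_genes(path: str | Path) -> list[GeneModel]:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df  # pyranges converts GTF to 0-based half-open
    if df.empty:
        raise FormatError(f"{path}: no records")
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        raise FormatError(f"{path}: no exon features")
    models = []
    for gene_id, grp in exons.groupby("gene_id", sort=True):
        strands = set(grp["Strand"])
        if len(strands) != 1 or not strands <= {"+", "-"}:
            raise FormatError(
                f"{path}: gene {gene_id}: unknown or inconsistent strand {strands}"
            )
        merged = _merge_blocks(zip(grp["Start"], grp["End"]))
        symbol = (
            str(grp["gene_name"].iloc[0]) if "gene_name" in grp.columns else str(gene_id)
        )
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                symbol=symbol,
                interval=GenomicInterval(
                    str(grp["Chromosome"].iloc[0]),
                    int(merged[0][0]),
                    int(merged[-1][1]),
                    strands.pop(),
                ),
                strand=str(grp["Strand"].iloc[0]),
                exonic_length=sum(e - s for s, e in merged),
                exons=tuple(merged),
            )
        )
    return models


def _read_bed12_genes(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            blocks = _merge_blocks(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            models.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    strand=strand,
                    exonic_length=sum(e - s for s, e in blocks),
                    exons=tuple(blocks),
                )
            )
    if not models:
        raise FormatError(f"{path}: no records")
    return models


def read_gene_models(path: str | Path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive on disk) or BED12."""
    if dialect == "gtf":
        return _read_gtf_genes(path)
    if dialect == "bed12":
        return _read_bed12_genes(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'gtf' or 'bed12')")


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            iv = g.interval
            exons = g.exons or ((iv.start, iv.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - iv.start) for s, e in exons)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Tag BED
# ---------------------------------------------------------------------------


def read_tags_bed(path: str | Path, factor: str) -> TagTrack:
    """Read single-end ChIP tags from BED; the tag position is the 5' end
    (start on +, end-1 on -; strandless records count as +)."""
    per_chrom: dict[str, list[int]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            strand = f[5] if len(f) >= 6 else "+"
            pos = start if strand != "-" else end - 1
            per_chrom.setdefault(f[0], []).append(pos)
            n += 1
    if n == 0:
        raise FormatError(f"{path}: empty tag file for factor {factor!r}")
    return TagTrack(factor, {c: np.array(p) for c, p in per_chrom.items()})


def write_tags_bed(track: TagTrack, path: str | Path, tag_length: int = 36) -> None:
    """Write tags as plus-strand BED6 stubs of ``tag_length`` bp."""
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for pos in track.positions[chrom]:
                fh.write(
                    f"{chrom}\t{pos}\t{pos + tag_length}\t{track.factor_name}\t0\t+\n"
                )


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path, pseudocount: float = 1.0) -> list[PWMRecord]:
    """Read JASPAR-style count matrices; counts become probabilities with a
    pseudocount (default 1) added to every cell, uniform background."""
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: malformed JASPAR file ({exc})") from exc
    records = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T
        if counts.size == 0:
            raise FormatError(f"{path}: motif {m.matrix_id} has no columns")
        probs = (counts + pseudocount) / (counts + pseudocount).sum(
            axis=1, keepdims=True
        )
        records.append(PWMRecord(motif_id=str(m.matrix_id or m.name), matrix=probs))
    if not records:
        raise FormatError(f"{path}: no motifs found")
    return records


def write_jaspar(counts_by_id: dict[str, np.ndarray], path: str | Path) -> None:
    """Write integer count matrices (positions x 4) in JASPAR format."""
    with open(path, "w") as fh:
        for motif_id, counts in counts_by_id.items():
            counts = np.asarray(counts)
            fh.write(f">{motif_id} {motif_id}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{int(c):3d}" for c in counts[:, i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "cell_line", "treatment", "replicate"]


def read_counts(counts_path: str | Path, sheet_path: str | Path) -> CountTable:
    """Read a gene x sample integer count TSV plus its sample sheet."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    float_view = df.to_numpy()
    if not np.issubdtype(float_view.dtype, np.number):
        raise FormatError(f"{counts_path}: non-numeric entries in count matrix")
    if not np.array_equal(float_view, np.floor(float_view)):
        raise FormatError(f"{counts_path}: counts must be integers")
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"{sheet_path}: missing columns {sorted(missing_cols)}")
    missing = [s for s in df.columns if s not in set(sheet["sample_id"])]
    if missing:
        raise FormatError(
            f"{sheet_path}: samples missing from sample sheet: {missing}"
        )
    sheet = (
        sheet.set_index("sample_id")
        .loc[list(df.columns)]
        .reset_index()[SHEET_COLUMNS]
    )
    return CountTable(
        gene_ids=[str(g) for g in df.index],
        samples=sheet,
        matrix=df.to_numpy().astype(np.int64),
    )


def write_counts(
    table: CountTable, counts_path: str | Path, sheet_path: str | Path
) -> None:
    df = table.to_frame()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    table.samples[SHEET_COLUMNS].to_csv(sheet_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV ('.' decimal, UTF-8, header row)."""
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
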
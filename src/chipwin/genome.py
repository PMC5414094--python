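"""Genome builds and gene annotations.

This module owns the coordinate conventions for the whole package:
0-based, half-open intervals everywhere internally.  SAM input (1-based)
is converted on read in :mod:`chipwin.reads`; BED output stays 0-based
half-open.  A gene's TSS is its transcription start in genomic
coordinates: ``txStart`` on the plus strand, ``txEnd - 1`` on the minus
strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

FEATURE_CLASSES = (
    "promoter",
    "5'UTR",
    "3'UTR",
    "coding exon",
    "intron",
    "intergenic",
)
# Precedence when a position falls in overlapping genes: the most
# promoter-like label wins; among equal labels the first gene in file
# order wins.
_PRECEDENCE = {c: i for i, c in enumerate(FEATURE_CLASSES)}


class AnnotationError(ValueError):
    """Malformed genome table or gene annotation."""


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names with lengths; defines the window grid."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise AnnotationError("duplicate chromosome names")
        for name, length in self.chroms:
            if not isinstance(length, int) or isinstance(length, bool) or length <= 0:
                raise AnnotationError(
                    f"chromosome {name!r}: length must be a positive integer, got {length!r}"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None

    def n_windows(self, chrom: str, window_size: int) -> int:
        """Number of windows tiling ``chrom``; the last window may be short."""
        return -(-self.length(chrom) // window_size)


def read_genome(path: str | Path) -> GenomeBuild:
    """Read a two-column whitespace-delimited chrom-sizes table."""
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 'name length'")
            name, raw = parts[0], parts[1]
            try:
                length = int(raw)
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer length {raw!r}"
                ) from None
            rows.append((name, length))
    if not rows:
        raise AnnotationError(f"{path}: empty genome table")
    return GenomeBuild(tuple(rows))


def write_genome(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


@dataclass
class GeneModel:
    """One transcript model: strand-aware TSS/TTS plus exon/CDS structure.

    ``tx_start``/``tx_end`` are the genomic transcript bounds (half-open),
    independent of strand; ``tss``/``tts`` are derived strand-aware.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.tx_start < self.tx_end:
            raise AnnotationError(f"gene {self.gene_id!r}: empty transcript span")
        prev_end = self.tx_start - 1
        for start, end in self.exons:
            if start < self.tx_start or end > self.tx_end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon [{start},{end}) outside transcript span"
                )
            if start >= end or start <= prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exons must be sorted, non-empty, non-overlapping"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        """Transcription start: tx_start (+) or tx_end - 1 (-)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def has_cds(self) -> bool:
        return (
            self.cds_start is not None
            and self.cds_end is not None
            and self.cds_start < self.cds_end
        )


def _read_refflat_line(parts: Sequence[str]) -> GeneModel:
    (gene_name, _name, chrom, strand, tx_start, tx_end,
     cds_start, cds_end, exon_count, exon_starts, exon_ends) = parts[:11]
    starts = [int(x) for x in exon_starts.rstrip(",").split(",") if x]
    ends = [int(x) for x in exon_ends.rstrip(",").split(",") if x]
    if len(starts) != int(exon_count) or len(ends) != int(exon_count):
        raise AnnotationError(f"gene {gene_name!r}: exon count mismatch")
    return GeneModel(
        gene_id=gene_name,
        chrom=chrom,
        strand=strand,
        tx_start=int(tx_start),
        tx_end=int(tx_end),
        exons=tuple(zip(starts, ends)),
        cds_start=int(cds_start),
        cds_end=int(cds_end),
    )


def _read_bed12_line(parts: Sequence[str]) -> GeneModel:
    chrom, start, end, name, _score, strand = parts[:6]
    thick_start, thick_end = int(parts[6]), int(parts[7])
    block_count = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in parts[11].rstrip(",").split(",") if x]
    if len(sizes) != block_count or len(offsets) != block_count:
        raise AnnotationError(f"record {name!r}: block count mismatch")
    start_i, end_i = int(start), int(end)
    exons = tuple((start_i + o, start_i + o + s) for o, s in zip(offsets, sizes))
    if exons and exons[-1][1] > end_i:
        raise AnnotationError(f"record {name!r}: blocks extend beyond chromEnd")
    return GeneModel(
        gene_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=start_i,
        tx_end=end_i,
        exons=exons,
        cds_start=thick_start,
        cds_end=thick_end,
    )


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a refFlat or BED12 annotation (dialect auto-detected per line count).

    refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    exonCount exonStarts exonEnds.  BED12 thickStart/thickEnd become the CDS.
    All coordinates 0-based half-open.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                if len(parts) >= 12 and parts[5] in ("+", "-"):
                    genes.append(_read_bed12_line(parts))
                elif len(parts) >= 11 and parts[3] in ("+", "-"):
                    genes.append(_read_refflat_line(parts))
                else:
                    raise AnnotationError("not refFlat (11 cols) or BED12 (12 cols)")
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            cds_s = g.cds_start if g.cds_start is not None else g.tx_end
            cds_e = g.cds_end if g.cds_end is not None else g.tx_end
            fh.write(
                f"{g.gene_id}\t{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t{cds_s}\t{cds_e}\t"
                f"{len(g.exons)}\t{starts}\t{ends}\n"
            )


def write_bed6(
    records: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


class GeneIndex:
    """Interval index over gene models for position classification.

    Each gene's searchable extent is its transcript span united with its
    promoter window, so a single stab query retrieves every gene that can
    label the position.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        genome: GenomeBuild,
        promoter_up: int = 3000,
        promoter_down: int = 0,
    ) -> None:
        self.genome = genome
        self.promoter_up = promoter_up
        self.promoter_down = promoter_down
        self._trees: dict[str, IntervalTree] = {}
        for order, gene in enumerate(genes):
            lo = min(gene.tx_start, self._promoter_bounds(gene)[0])
            hi = max(gene.tx_end, self._promoter_bounds(gene)[1])
            lo = max(lo, 0)
            hi = min(hi, genome.length(gene.chrom))
            if lo >= hi:
                continue
            self._trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, (order, gene))

    def _promoter_bounds(self, gene: GeneModel) -> tuple[int, int]:
        if gene.strand == "+":
            return gene.tss - self.promoter_up, gene.tss + self.promoter_down
        return gene.tss + 1 - self.promoter_down, gene.tss + 1 + self.promoter_up

    def _classify_one(self, pos: int, gene: GeneModel) -> str:
        # signed offset in transcription direction; promoter is
        # [-promoter_up, promoter_down) relative to the TSS
        d = pos - gene.tss if gene.strand == "+" else gene.tss - pos
        if -self.promoter_up <= d < self.promoter_down:
            return "promoter"
        if not gene.tx_start <= pos < gene.tx_end:
            return "intergenic"
        in_exon = any(s <= pos < e for s, e in gene.exons)
        if not in_exon:
            return "intron"
        if not gene.has_cds:
            return "coding exon"  # non-coding models: whole exon treated as exonic
        if gene.cds_start <= pos < gene.cds_end:
            return "coding exon"
        before_cds = pos < gene.cds_start
        if gene.strand == "+":
            return "5'UTR" if before_cds else "3'UTR"
        return "3'UTR" if before_cds else "5'UTR"

    def classify(self, chrom: str, pos: int) -> str:
        """Feature class of a genomic position under the precedence rule."""
        if chrom not in self.genome:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.genome.length(chrom):
            raise AnnotationError(f"position {pos} outside {chrom}")
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic"
        best = "intergenic"
        best_key = (_PRECEDENCE[best], -1)
        for iv in sorted(tree.at(pos), key=lambda iv: iv.data[0]):
            order, gene = iv.data
            cls = self._classify_one(pos, gene)
            key = (_PRECEDENCE[cls], order)
            if key[0] < best_key[0]:
                best, best_key = cls, key
        return best


def classify_position(
    pos: int,
    chrom: str,
    genes: Sequence[GeneModel] | GeneIndex,
    genome: GenomeBuild | None = None,
    promoter_up: int = 3000,
    promoter_down: int = 0,
) -> str:
    """Classify one genomic position; builds a throwaway index if given a list.

    For repeated queries build a :class:`GeneIndex` once and call
    :meth:`GeneIndex.classify`.
    """
    if isinstance(genes, GeneIndex):
        return genes.classify(chrom, pos)
    if genome is None:
        raise ValueError("genome required when passing a raw gene list")
    idx = GeneIndex(genes, genome, promoter_up, promoter_down)
    return idx.classify(chrom, pos)


def tss_anchors(genes: Iterable[GeneModel]) -> list[tuple[str, int, str]]:
    """(chrom, tss, strand) anchor per gene, in input order."""
    return [(g.chrom, g.tss, g.strand) for g in genes]
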
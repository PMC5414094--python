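"""Aligned-read input, mapping filters, deduplication, counting positions.

Reads come in as SAM (via pysam) or 6-column BED of read placements.
Each retained read is reduced to its 5' end (`start5`), then optionally
shifted toward the fragment midpoint before window counting.  The
retention rules mirror standard single-end ChIP-seq practice: keep only
uniquely mapping reads with at most two mismatches, and count at most
one read per (chrom, 5' position, strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .genome import AnnotationError, GenomeBuild


class ReadError(ValueError):
    """Malformed or out-of-bounds read record."""


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One single-end alignment reduced to the fields the pipeline uses.

    ``start5`` is the 0-based coordinate of the 5' end of the read:
    the leftmost aligned base on the plus strand, the rightmost on the
    minus strand.
    """

    chrom: str
    start5: int
    strand: str
    length: int = 50
    mismatches: int | None = None
    unique: bool = True


@dataclass(frozen=True)
class ReadSet:
    """Filtered, deduplicated reads for one sample."""

    reads: tuple[AlignedRead, ...]
    library_size: int
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.library_size != len(self.reads):
            raise ReadError("library_size must equal the retained read count")

    def __len__(self) -> int:
        return self.library_size


def _check_bounds(read: AlignedRead, genome: GenomeBuild) -> None:
    if read.chrom not in genome:
        raise ReadError(f"read on unknown chromosome {read.chrom!r}")
    clen = genome.length(read.chrom)
    if not 0 <= read.start5 < clen:
        raise ReadError(
            f"read 5' end {read.start5} outside {read.chrom} (length {clen})"
        )


def _iter_sam(path: str | Path, genome: GenomeBuild) -> Iterator[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            if chrom is None or chrom not in genome:
                raise ReadError(f"read on unknown chromosome {chrom!r}")
            if aln.reference_end is None:
                continue
            if aln.reference_end > genome.length(chrom):
                raise ReadError(
                    f"read {aln.query_name!r} extends beyond end of {chrom}"
                )
            start5 = aln.reference_start if not aln.is_reverse else aln.reference_end - 1
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            length = aln.query_length or (aln.reference_end - aln.reference_start)
            yield AlignedRead(
                chrom=chrom,
                start5=start5,
                strand="-" if aln.is_reverse else "+",
                length=length,
                mismatches=nm,
                # uniqueness is not recoverable from arbitrary SAM; MAPQ >= 1
                # is the documented proxy when no multi-hit tag exists
                unique=(aln.mapping_quality or 0) >= 1,
            )


def _iter_bed6(path: str | Path, genome: GenomeBuild) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ReadError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, _name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ReadError(f"{path}:{lineno}: unknown strand {strand!r}")
            start_i, end_i = int(start), int(end)
            if chrom not in genome:
                raise ReadError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end_i > genome.length(chrom) or start_i < 0:
                raise ReadError(f"{path}:{lineno}: read outside {chrom}")
            read = AlignedRead(
                chrom=chrom,
                start5=start_i if strand == "+" else end_i - 1,
                strand=strand,
                length=end_i - start_i,
            )
            yield read


def read_alignments(
    path: str | Path, genome: GenomeBuild, fmt: str | None = None
) -> list[AlignedRead]:
    """Read SAM or BED6 alignments; drops unmapped/secondary/supplementary.

    ``fmt`` is "sam" or "bed"; inferred from the file extension when None.
    """
    if fmt is None:
        fmt = "sam" if str(path).endswith((".sam", ".bam")) else "bed"
    if fmt == "sam":
        return list(_iter_sam(path, genome))
    if fmt == "bed":
        return list(_iter_bed6(path, genome))
    raise ValueError(f"unknown alignment format {fmt!r}")


def filter_reads(
    reads: Iterable[AlignedRead],
    max_mismatch: int | float | None = 2,
    require_unique: bool = True,
) -> list[AlignedRead]:
    """Keep uniquely mapping reads with at most ``max_mismatch`` mismatches.

    Reads lacking a mismatch count pass the mismatch filter vacuously.
    ``max_mismatch=None`` (or inf) disables the mismatch filter.
    """
    if max_mismatch is None:
        max_mismatch = math.inf
    out = []
    for r in reads:
        if require_unique and not r.unique:
            continue
        if r.mismatches is not None and r.mismatches > max_mismatch:
            continue
        out.append(r)
    return out


def deduplicate(
    reads: Iterable[AlignedRead], sample_label: str = ""
) -> ReadSet:
    """Retain at most one read per (chrom, start5, strand) key.

    The key includes strand so that bidirectional fragment evidence at
    one position is preserved.  Idempotent.
    """
    seen: set[tuple[str, int, str]] = set()
    kept: list[AlignedRead] = []
    for r in reads:
        key = (r.chrom, r.start5, r.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return ReadSet(reads=tuple(kept), library_size=len(kept), sample_label=sample_label)


def counting_position(
    read: AlignedRead, genome: GenomeBuild, shift: int = 150
) -> tuple[str, int]:
    """Shift the 5' end ``shift`` bp in the 3' direction, clamped to the chrom.

    The default 150 bp is half the 300 bp midpoint of a 200-500 bp
    sonication range, so counts approximate fragment midpoints.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    pos = read.start5 + shift if read.strand == "+" else read.start5 - shift
    return read.chrom, min(max(pos, 0), genome.length(read.chrom) - 1)


def load_sample(
    path: str | Path,
    genome: GenomeBuild,
    sample_label: str = "",
    max_mismatch: int | None = 2,
    require_unique: bool = True,
    fmt: str | None = None,
) -> tuple[ReadSet, dict[str, int]]:
    """Read, filter and deduplicate one sample; returns attrition counts."""
    raw = read_alignments(path, genome, fmt=fmt)
    filtered = filter_reads(raw, max_mismatch=max_mismatch, require_unique=require_unique)
    rs = deduplicate(filtered, sample_label=sample_label or str(path))
    stats = {
        "mapped": len(raw),
        "after_filter": len(filtered),
        "after_dedup": rs.library_size,
    }
    return rs, stats


def write_bed6_reads(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Write reads as BED6 read placements (span = aligned length)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = r.start5, r.start5 + r.length
            else:
                start, end = r.start5 - r.length + 1, r.start5 + 1
            fh.write(f"{r.chrom}\t{max(start, 0)}\t{end}\tread{i}\t0\t{r.strand}\n")
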
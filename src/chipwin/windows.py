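"""Fixed-width window grids and per-window read counts.

The genome is tiled with non-overlapping 100-bp windows (half-open,
window ``w`` spans ``[w*s, (w+1)*s)``); the final partial window of each
chromosome is retained so that every retained read lands in exactly one
window and counts sum to the library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .genome import GenomeBuild
from .reads import ReadSet, counting_position


def window_index(pos: int, window_size: int) -> int:
    """Ordinal of the window containing ``pos``: floor(pos / window_size)."""
    if pos < 0:
        raise ValueError("position must be >= 0")
    return pos // window_size


@dataclass
class WindowTrack:
    """Per-chromosome vectors of deduplicated read counts per window."""

    genome: GenomeBuild
    window_size: int
    counts: dict[str, np.ndarray]
    library_size: int
    sample_label: str = ""

    def __post_init__(self) -> None:
        for chrom, vec in self.counts.items():
            expected = self.genome.n_windows(chrom, self.window_size)
            if len(vec) != expected:
                raise ValueError(
                    f"{chrom}: {len(vec)} windows, grid needs {expected}"
                )

    @property
    def total_count(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.window_size == other.window_size
            and self.genome.chroms == other.genome.chroms
        )

    def window_bounds(self, chrom: str, window: int) -> tuple[int, int]:
        s = self.window_size
        return window * s, min((window + 1) * s, self.genome.length(chrom))


def count_windows(
    reads: ReadSet,
    genome: GenomeBuild,
    window_size: int = 100,
    shift: int = 150,
) -> WindowTrack:
    """Bin each read's shifted counting position into the window grid."""
    per_chrom: dict[str, list[int]] = {name: [] for name in genome.names}
    for read in reads.reads:
        chrom, pos = counting_position(read, genome, shift=shift)
        per_chrom[chrom].append(pos // window_size)
    counts = {
        name: np.bincount(
            np.asarray(idx, dtype=np.int64),
            minlength=genome.n_windows(name, window_size),
        ).astype(np.int64)
        for name, idx in per_chrom.items()
    }
    return WindowTrack(
        genome=genome,
        window_size=window_size,
        counts=counts,
        library_size=reads.library_size,
        sample_label=reads.sample_label,
    )


def to_bedgraph(
    track: WindowTrack,
    path: str | Path,
    normalize: Literal["raw", "per-million"] = "raw",
    track_line: bool = False,
) -> None:
    """Write one bedGraph record per nonzero window."""
    if normalize == "per-million" and track.library_size == 0:
        raise ValueError("per-million normalization undefined for empty library")
    scale = 1e6 / track.library_size if normalize == "per-million" else 1
    with open(path, "w") as fh:
        if track_line:
            fh.write(f'track type=bedGraph name="{track.sample_label}"\n')
        for chrom in track.genome.names:
            vec = track.counts[chrom]
            for w in np.flatnonzero(vec):
                start, end = track.window_bounds(chrom, int(w))
                value = vec[w] * scale
                if normalize == "raw":
                    fh.write(f"{chrom}\t{start}\t{end}\t{int(vec[w])}\n")
                else:
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def to_tsv(track: WindowTrack, path: str | Path, skip_zero: bool = True) -> None:
    """Write (chrom, start, end, count) rows for the window grid."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\n")
        for chrom in track.genome.names:
            vec = track.counts[chrom]
            idx = np.flatnonzero(vec) if skip_zero else range(len(vec))
            for w in idx:
                start, end = track.window_bounds(chrom, int(w))
                fh.write(f"{chrom}\t{start}\t{end}\t{int(vec[w])}\n")
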
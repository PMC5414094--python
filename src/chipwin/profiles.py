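"""Average signal profiles around anchor sets (TSSs or a gene set).

Signal is windowed read counts converted to reads-per-million and
resampled onto a relative grid around each anchor by window-overlap
fraction; minus-strand anchors are reversed so upstream is always to
the left.  The per-anchor matrix is retained so that two conditions can
be compared with anchor-level bootstrap bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GeneModel
from .windows import WindowTrack

Anchor = tuple[str, int, str]


@dataclass
class Profile:
    """Mean per-million signal per relative bin around a set of anchors."""

    anchor_set_label: str
    flank: int
    bin: int
    values: np.ndarray
    n_anchors: int
    per_anchor_matrix: np.ndarray | None = None
    n_edge_anchors: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(-self.flank + self.bin / 2, self.flank, self.bin)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_center\tmean_rpm\n")
            for c, v in zip(self.bin_centers, self.values):
                fh.write(f"{c:g}\t{v:.6f}\n")


def _fractional_counts(
    counts: np.ndarray, window_size: int, chrom_len: int, edges: np.ndarray
) -> np.ndarray:
    """Fractional read count per [edges[i], edges[i+1]) interval.

    Counts are treated as uniformly spread within their window; positions
    outside the chromosome contribute zero (edge padding).
    """
    x = np.clip(edges, 0, chrom_len)
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    w = np.minimum(x // window_size, len(counts) - 1).astype(int)
    frac = cum[w] + counts[w] * (x - w * window_size) / window_size
    # beyond the grid end (short last window), clamp to the total
    frac = np.minimum(frac, cum[-1])
    return np.diff(frac)


def build_profile(
    track: WindowTrack,
    anchors: Sequence[Anchor],
    flank: int = 5000,
    bin: int = 100,
    label: str = "",
    keep_matrix: bool = True,
) -> Profile:
    """Average per-million signal on a +/-flank grid around each anchor.

    Each relative bin's value is the fractional read count overlapping
    the bin, in reads per million mapped reads; bins extending past the
    chromosome are zero-padded and the anchor is flagged.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    if flank % bin:
        raise ValueError("bin must divide flank")
    if track.library_size <= 0:
        raise ValueError("per-million scaling undefined for empty library")
    n_bins = 2 * flank // bin
    rel_edges = np.arange(-flank, flank + bin, bin, dtype=float)
    scale = 1e6 / track.library_size
    mat = np.zeros((len(anchors), n_bins))
    n_edge = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        chrom_len = track.genome.length(chrom)
        if pos - flank < 0 or pos + flank > chrom_len:
            n_edge += 1
        row = _fractional_counts(
            track.counts[chrom], track.window_size, chrom_len, pos + rel_edges
        )
        if strand == "-":
            row = row[::-1]
        mat[i] = row * scale
    return Profile(
        anchor_set_label=label,
        flank=flank,
        bin=bin,
        values=mat.mean(axis=0),
        n_anchors=len(anchors),
        per_anchor_matrix=mat if keep_matrix else None,
        n_edge_anchors=n_edge,
    )


@dataclass
class ProfileComparison:
    """Per-bin difference and log2 ratio of two profiles with bootstrap bands."""

    bin_centers: np.ndarray
    difference: np.ndarray
    log2_ratio: np.ndarray
    diff_band: np.ndarray  # (2, n_bins): 2.5 / 97.5 percentiles
    ratio_band: np.ndarray
    n_boot: int
    pseudocount: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "bin_center\tdifference\tdiff_lo\tdiff_hi\t"
                "log2_ratio\tratio_lo\tratio_hi\n"
            )
            for i, c in enumerate(self.bin_centers):
                fh.write(
                    f"{c:g}\t{self.difference[i]:.6f}\t{self.diff_band[0, i]:.6f}\t"
                    f"{self.diff_band[1, i]:.6f}\t{self.log2_ratio[i]:.6f}\t"
                    f"{self.ratio_band[0, i]:.6f}\t{self.ratio_band[1, i]:.6f}\n"
                )


def compare_profiles(
    a: Profile,
    b: Profile,
    pseudocount: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> ProfileComparison:
    """Per-bin ``b - a`` and ``log2((b+c)/(a+c))`` with bootstrap 95% bands.

    The two profiles must share the grid and anchor set; anchors are
    resampled jointly (paired bootstrap), default 1000 resamples.
    """
    if (a.flank, a.bin, a.n_anchors) != (b.flank, b.bin, b.n_anchors):
        raise ValueError("profiles must share grid and anchor set")
    if a.per_anchor_matrix is None or b.per_anchor_matrix is None:
        raise ValueError("compare_profiles needs per-anchor matrices")
    c = pseudocount
    diff = b.values - a.values
    ratio = np.log2((b.values + c) / (a.values + c))
    rng = np.random.default_rng(seed)
    n = a.n_anchors
    boot_diff = np.empty((n_boot, len(diff)))
    boot_ratio = np.empty((n_boot, len(diff)))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        am = a.per_anchor_matrix[idx].mean(axis=0)
        bm = b.per_anchor_matrix[idx].mean(axis=0)
        boot_diff[i] = bm - am
        boot_ratio[i] = np.log2((bm + c) / (am + c))
    return ProfileComparison(
        bin_centers=a.bin_centers,
        difference=diff,
        log2_ratio=ratio,
        diff_band=np.percentile(boot_diff, [2.5, 97.5], axis=0),
        ratio_band=np.percentile(boot_ratio, [2.5, 97.5], axis=0),
        n_boot=n_boot,
        pseudocount=c,
    )


def load_gene_set(
    path: str | Path, genes: Sequence[GeneModel]
) -> tuple[list[Anchor], list[str]]:
    """TSS anchors for the gene ids listed one per line in ``path``.

    Duplicate ids collapse to a single anchor (with a warning); missing
    ids are returned, not fatal; zero matches is an error.
    """
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    if not ids:
        raise ValueError(f"{path}: empty gene-set file")
    seen: list[str] = []
    dupes = set()
    for gid in ids:
        if gid in seen:
            dupes.add(gid)
        else:
            seen.append(gid)
    if dupes:
        warnings.warn(f"duplicate gene ids collapsed: {sorted(dupes)}")
    by_id = {}
    for g in genes:
        by_id.setdefault(g.gene_id, g)
    anchors = [(by_id[g].chrom, by_id[g].tss, by_id[g].strand) for g in seen if g in by_id]
    missing = [g for g in seen if g not in by_id]
    if not anchors:
        raise ValueError(f"{path}: no gene ids matched the annotation")
    return anchors, missing


def plot_profiles(
    profiles: Sequence[Profile], path: str | Path, title: str = ""
) -> None:
    """Line plot of mean profiles (one line per profile) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.bin_centers, p.values, label=p.anchor_set_label or None)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean signal (reads per million)")
    if title:
        ax.set_title(title)
    if any(p.anchor_set_label for p in profiles):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
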
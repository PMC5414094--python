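"""Peak annotation: gene assignment, TSS distances, feature and chromosome stats.

A gene is "bound" when any peak interval lies within a fixed radius
(default 5 kb) of its TSS, measured peak-edge-to-TSS.  Histograms and
feature classification use the peak summit as the peak's point
representative, so every peak carries exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import FEATURE_CLASSES, GeneIndex, GeneModel, GenomeBuild
from .peaks import Peak, PeakSet


@dataclass(frozen=True)
class GeneBinding:
    """Binding call for one gene: bound flag plus signed TSS distance.

    ``distance_to_tss`` is the gap from the TSS to the nearest peak edge
    (0 when the TSS lies inside a peak), signed in transcription
    direction: negative means the peak is upstream of the TSS.
    """

    gene_id: str
    bound: bool
    closest_peak: Peak | None
    distance_to_tss: int | None


def _nearest_peak(
    tss: int, starts: np.ndarray, ends: np.ndarray, peaks: Sequence[Peak]
) -> tuple[Peak, int]:
    """Nearest peak to a point, with genomic signed gap (negative = peak left)."""
    i = int(np.searchsorted(starts, tss, side="right")) - 1
    best: tuple[int, Peak] | None = None
    for j in (i, i + 1):
        if 0 <= j < len(peaks):
            if starts[j] <= tss < ends[j]:
                return peaks[j], 0
            gap = int(starts[j] - tss) if tss < starts[j] else -int(tss - ends[j])
            if best is None or abs(gap) < abs(best[0]):
                best = (gap, peaks[j])
    assert best is not None
    return best[1], best[0]


def assign_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    tss_radius: float = 5000,
) -> list[GeneBinding]:
    """Per gene: bound flag and signed distance to the nearest peak edge.

    Bound iff the gap between the TSS and the nearest peak interval is
    <= ``tss_radius`` (strict beyond the radius).
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    arrays = {
        c: (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            ps,
        )
        for c, ps in by_chrom.items()
    }
    out: list[GeneBinding] = []
    for g in genes:
        if g.chrom not in arrays:
            out.append(GeneBinding(g.gene_id, False, None, None))
            continue
        starts, ends, ps = arrays[g.chrom]
        peak, gap = _nearest_peak(g.tss, starts, ends, ps)
        signed = gap if g.strand == "+" else -gap
        out.append(
            GeneBinding(
                gene_id=g.gene_id,
                bound=abs(gap) <= tss_radius,
                closest_peak=peak,
                distance_to_tss=signed,
            )
        )
    return out


def write_gene_binding(bindings: Sequence[GeneBinding], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbound\tdistance_to_tss\tpeak_chrom\tpeak_start\tpeak_end\n")
        for b in bindings:
            if b.closest_peak is None:
                fh.write(f"{b.gene_id}\t0\tNA\tNA\tNA\tNA\n")
            else:
                p = b.closest_peak
                fh.write(
                    f"{b.gene_id}\t{int(b.bound)}\t{b.distance_to_tss}\t"
                    f"{p.chrom}\t{p.start}\t{p.end}\n"
                )


@dataclass
class TssDistanceHistogram:
    """Signed summit-to-nearest-TSS distances, binned, with overflow pool."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: int
    n_peaks: int
    frac_within_5kb: float
    frac_within_2kb: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                fh.write(f"{int(lo)}\t{int(hi)}\t{int(c)}\n")
            fh.write(f"overflow\toverflow\t{self.overflow}\n")


def tss_distance_histogram(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    max_dist: int = 10000,
    bin: int = 1000,
) -> TssDistanceHistogram:
    """Distances from peak summits to their nearest TSS, strand-aware sign.

    Positive = summit downstream of the TSS in transcription direction.
    Summits farther than ``max_dist`` (or on gene-free chromosomes) go to
    the overflow pool.  Also reports the fraction of all peaks within
    +/-5 kb and +/-2 kb of a TSS.
    """
    if max_dist % bin:
        raise ValueError("bin must divide max_dist")
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        gs = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.tss)
        tss_by_chrom[chrom] = (
            np.array([g.tss for g in gs]),
            np.array([1 if g.strand == "+" else -1 for g in gs]),
        )
    dists: list[int] = []
    overflow = 0
    for p in peaks:
        if p.chrom not in tss_by_chrom or len(tss_by_chrom[p.chrom][0]) == 0:
            overflow += 1
            continue
        tss, sign = tss_by_chrom[p.chrom]
        i = int(np.searchsorted(tss, p.summit))
        cands = [j for j in (i - 1, i) if 0 <= j < len(tss)]
        j = min(cands, key=lambda j: abs(p.summit - tss[j]))
        d = int((p.summit - tss[j]) * sign[j])
        if -max_dist <= d < max_dist:
            dists.append(d)
        else:
            overflow += 1
    edges = np.arange(-max_dist, max_dist + bin, bin)
    counts, _ = np.histogram(dists, bins=edges)
    n = len(peaks)
    abs_d = np.abs(np.array(dists)) if dists else np.array([])
    return TssDistanceHistogram(
        bin_edges=edges,
        counts=counts,
        overflow=overflow,
        n_peaks=n,
        frac_within_5kb=float((abs_d <= 5000).sum() / n) if n else 0.0,
        frac_within_2kb=float((abs_d <= 2000).sum() / n) if n else 0.0,
    )


@dataclass
class FeatureDistribution:
    """Fraction of peaks (or sampled windows) per genomic feature class."""

    fractions: dict[str, float]
    n_items: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tfraction\n")
            for cls in FEATURE_CLASSES:
                fh.write(f"{cls}\t{self.fractions[cls]:.6f}\n")


def feature_distribution(
    items: PeakSet | int,
    genes: Sequence[GeneModel],
    genome: GenomeBuild,
    promoter_up: int = 3000,
    promoter_down: int = 0,
    seed: int | None = 0,
    window_size: int = 100,
) -> FeatureDistribution:
    """Classify peak summits (or a uniform random window sample) by feature.

    Pass a :class:`PeakSet` to classify each peak by its summit, or an
    integer ``n`` to classify the midpoints of ``n`` uniformly sampled
    windows (seeded) — the input-like baseline the promoter fraction of
    peaks is compared against.
    """
    index = GeneIndex(genes, genome, promoter_up=promoter_up, promoter_down=promoter_down)
    if isinstance(items, PeakSet):
        if len(items) == 0:
            raise ValueError("no peaks to classify")
        positions = [(p.chrom, p.summit) for p in items]
    else:
        if items <= 0:
            raise ValueError("window sample size must be positive")
        rng = np.random.default_rng(seed)
        lens = genome.lengths
        chrom_p = np.array([lens[c] for c in genome.names], dtype=float)
        chrom_p /= chrom_p.sum()
        positions = []
        for _ in range(items):
            chrom = genome.names[rng.choice(len(chrom_p), p=chrom_p)]
            w = rng.integers(0, genome.n_windows(chrom, window_size))
            mid = min(int(w) * window_size + window_size // 2, lens[chrom] - 1)
            positions.append((chrom, mid))
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for chrom, pos in positions:
        counts[index.classify(chrom, pos)] += 1
    n = len(positions)
    return FeatureDistribution(
        fractions={cls: counts[cls] / n for cls in FEATURE_CLASSES}, n_items=n
    )


@dataclass
class ChromEnrichment:
    """Per-chromosome peak counts vs length-proportional expectation."""

    chroms: list[str]
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    p_value: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tobserved\texpected\tratio\tp_value\n")
            for c, o, e, r, p in zip(
                self.chroms, self.observed, self.expected, self.ratio, self.p_value
            ):
                fh.write(f"{c}\t{int(o)}\t{e:.4f}\t{r:.4f}\t{p:.6g}\n")


def chromosome_enrichment(peaks: PeakSet, genome: GenomeBuild) -> ChromEnrichment:
    """Two-sided binomial test of peak counts against chromosome length.

    The null assigns each peak to a chromosome with probability
    proportional to its length.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks")
    total = len(peaks)
    obs = np.array([sum(p.chrom == c for p in peaks) for c in genome.names])
    lens = np.array([genome.length(c) for c in genome.names], dtype=float)
    probs = lens / lens.sum()
    exp = total * probs
    ratio = np.divide(obs, exp, out=np.full_like(exp, np.nan), where=exp > 0)
    pvals = np.array(
        [
            stats.binomtest(int(o), total, pr, alternative="two-sided").pvalue
            for o, pr in zip(obs, probs)
        ]
    )
    return ChromEnrichment(
        chroms=list(genome.names), observed=obs, expected=exp, ratio=ratio, p_value=pvals
    )
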
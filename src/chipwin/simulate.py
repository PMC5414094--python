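"""Synthetic ChIP/input read generator with known ground truth.

Emulates the statistical structure the windowed-Poisson caller assumes:
a small multi-chromosome genome; an input background that is Poisson
per window with a smooth lognormal regional rate multiplier shared
between ChIP and input (so per-window input genuinely informs the
expectation); ChIP-only spike components at a configurable fold
enrichment in fixed-width regions centred on designated target-gene
TSSs; fragments in a sonication-like 200-500 bp range, each yielding a
single-end 50-bp read from a uniformly chosen fragment end.  A second
condition can remove or add spikes, emulating a knockdown contrast.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d

from .genome import GeneModel, GenomeBuild, write_genome, write_refflat
from .reads import AlignedRead, ReadSet, deduplicate, write_bed6_reads
from .peaks import PeakSet

SAMPLE_LABELS = ("input_cond1", "chip_cond1", "input_cond2", "chip_cond2")


@dataclass
class SimulationConfig:
    """Study conditions for the generator; the seed fully determines output."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_genes: int = 200
    n_target_genes: int = 10
    min_tss_spacing: int = 2000
    fragment_length: tuple[int, int] = (200, 500)
    read_length: int = 50
    chip_depth: int = 100_000
    input_depth: int = 100_000
    background_rate: float | None = None  # reads/bp; overrides depths when set
    fold_enrichment: float = 10.0
    spike_width: int = 5  # windows, centred at target TSSs
    window_size: int = 100
    condition_effect: Literal["none", "remove_spikes", "add_spikes"] = "remove_spikes"
    regional_rate_sd: float = 0.2  # log-sd of the smooth background multiplier
    regional_smooth_windows: float = 20.0

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_target_genes < 0:
            raise ValueError("gene counts must be >= 0")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes cannot exceed n_genes")
        if self.n_genes == 0 and self.n_target_genes > 0:
            raise ValueError("cannot place target spikes without genes")
        if self.fold_enrichment < 1:
            raise ValueError("fold_enrichment must be >= 1")
        lo, hi = self.fragment_length
        if not 0 < lo <= hi:
            raise ValueError("invalid fragment length range")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        max_span = self.spike_width * self.window_size
        if max_span > min(self.chrom_lengths):
            raise ValueError("spike regions exceed the genome")


@dataclass(frozen=True)
class SpikeRegion:
    chrom: str
    start: int
    end: int
    fold: float
    gene_id: str
    in_condition1: bool
    in_condition2: bool


@dataclass
class GroundTruth:
    """Spiked enrichment regions and the target genes they sit on."""

    regions: list[SpikeRegion]
    target_gene_ids: list[str]

    def regions_in(self, condition: int) -> list[SpikeRegion]:
        key = "in_condition1" if condition == 1 else "in_condition2"
        return [r for r in self.regions if getattr(r, key)]


@dataclass
class SimulationResult:
    genome: GenomeBuild
    genes: list[GeneModel]
    samples: dict[str, ReadSet]
    truth: GroundTruth
    config: SimulationConfig


def _place_genes(
    rng: np.random.Generator, genome: GenomeBuild, config: SimulationConfig
) -> list[GeneModel]:
    margin = 25_000
    lengths = genome.lengths
    total = genome.total_length
    genes: list[GeneModel] = []
    remaining = config.n_genes
    names = genome.names
    for k, chrom in enumerate(names):
        clen = lengths[chrom]
        n = remaining if k == len(names) - 1 else round(config.n_genes * clen / total)
        n = min(n, remaining)
        lo, hi = min(margin, clen // 4), clen - min(margin, clen // 4)
        slots = np.arange(lo, hi, config.min_tss_spacing)
        if len(slots) < n:
            raise ValueError(f"{chrom}: too short for {n} genes at the required spacing")
        tss_positions = np.sort(rng.choice(slots, size=n, replace=False))
        for tss in tss_positions:
            gid = f"gene{len(genes):04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2000, 20001))
            tss = int(tss)
            if strand == "+":
                tx_start, tx_end = tss, min(tss + glen, clen)
            else:
                tx_start, tx_end = max(tss + 1 - glen, 0), tss + 1
            span = tx_end - tx_start
            mid = tx_start + span // 2
            exons = (
                (tx_start, tx_start + 200),
                (max(mid - 250, tx_start + 300), min(mid + 250, tx_end - 300)),
                (tx_end - 200, tx_end),
            )
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                    cds_start=tx_start + 300,
                    cds_end=tx_end - 300,
                )
            )
        remaining -= n
    return genes


def _smooth_lognormal_field(
    rng: np.random.Generator, n: int, sd: float, smooth: float
) -> np.ndarray:
    """Mean-one lognormal multiplier with smooth spatial correlation."""
    z = gaussian_filter1d(rng.standard_normal(n), smooth, mode="wrap")
    s = z.std()
    if s > 0 and sd > 0:
        z = z / s * sd
    else:
        z = np.zeros(n)
    return np.exp(z - sd**2 / 2)


def _spike_regions_for(
    genes: Sequence[GeneModel],
    gene_ids: Sequence[str],
    genome: GenomeBuild,
    config: SimulationConfig,
    flags: tuple[bool, bool],
) -> list[SpikeRegion]:
    by_id = {g.gene_id: g for g in genes}
    s = config.window_size
    out = []
    for gid in gene_ids:
        g = by_id[gid]
        n_win = genome.n_windows(g.chrom, s)
        sw = g.tss // s - config.spike_width // 2
        sw = max(0, min(sw, n_win - config.spike_width))
        start = sw * s
        end = min((sw + config.spike_width) * s, genome.length(g.chrom))
        out.append(
            SpikeRegion(g.chrom, start, end, config.fold_enrichment, gid, *flags)
        )
    return out


def _draw_reads(
    rng: np.random.Generator,
    genome: GenomeBuild,
    rates: dict[str, np.ndarray],
    config: SimulationConfig,
    label: str,
) -> ReadSet:
    """Poisson counts per window -> fragments -> one single-end read each."""
    s = config.window_size
    fmin, fmax = config.fragment_length
    rl = config.read_length
    reads: list[AlignedRead] = []
    for chrom in genome.names:
        clen = genome.length(chrom)
        counts = rng.poisson(rates[chrom])
        widx = np.repeat(np.arange(len(counts)), counts)
        n = len(widx)
        if n == 0:
            continue
        widths = np.minimum((widx + 1) * s, clen) - widx * s
        mid = widx * s + rng.random(n) * widths
        frag = rng.integers(fmin, fmax + 1, n)
        strand_plus = rng.random(n) < 0.5
        left = np.floor(mid - frag / 2).astype(np.int64)
        start5 = np.where(strand_plus, left, left + frag - 1)
        start5 = np.where(
            strand_plus,
            np.clip(start5, 0, clen - rl),
            np.clip(start5, rl - 1, clen - 1),
        )
        mm = rng.integers(0, 3, n)  # 0-2 mismatches, all pass the default filter
        for p5, plus, m in zip(start5, strand_plus, mm):
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    start5=int(p5),
                    strand="+" if plus else "-",
                    length=rl,
                    mismatches=int(m),
                    unique=True,
                )
            )
    return deduplicate(reads, sample_label=label)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate genome, annotation, ground truth, and 4 read sets.

    Samples: input and ChIP for condition 1 (spikes at target TSSs) and
    condition 2 (spikes modified per ``condition_effect``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = GenomeBuild(
        tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(config.chrom_lengths))
    )
    genes = _place_genes(rng, genome, config)

    target_ids = (
        sorted(rng.choice([g.gene_id for g in genes], config.n_target_genes, replace=False))
        if config.n_target_genes
        else []
    )
    if config.condition_effect == "none":
        regions = _spike_regions_for(genes, target_ids, genome, config, (True, True))
        added_ids: list[str] = []
    elif config.condition_effect == "remove_spikes":
        regions = _spike_regions_for(genes, target_ids, genome, config, (True, False))
        added_ids = []
    else:  # add_spikes
        regions = _spike_regions_for(genes, target_ids, genome, config, (True, True))
        pool = [g.gene_id for g in genes if g.gene_id not in set(target_ids)]
        n_add = min(config.n_target_genes, len(pool))
        added_ids = sorted(rng.choice(pool, n_add, replace=False)) if n_add else []
        regions += _spike_regions_for(genes, added_ids, genome, config, (False, True))

    s = config.window_size
    field_by_chrom = {
        chrom: _smooth_lognormal_field(
            rng,
            genome.n_windows(chrom, s),
            config.regional_rate_sd,
            config.regional_smooth_windows,
        )
        for chrom in genome.names
    }
    widths = {
        chrom: np.minimum(
            (np.arange(genome.n_windows(chrom, s)) + 1) * s, genome.length(chrom)
        )
        - np.arange(genome.n_windows(chrom, s)) * s
        for chrom in genome.names
    }
    base = {c: field_by_chrom[c] * widths[c] for c in genome.names}

    def fold_factors(condition: int) -> dict[str, np.ndarray]:
        out = {c: np.ones_like(base[c]) for c in genome.names}
        for r in (x for x in regions if getattr(x, f"in_condition{condition}")):
            w0, w1 = r.start // s, -(-r.end // s)
            out[r.chrom][w0:w1] = r.fold
        return out

    def scaled_rates(intensity: dict[str, np.ndarray], depth: int) -> dict[str, np.ndarray]:
        if config.background_rate is not None:
            # explicit reads/bp overrides the depth target
            return {c: intensity[c] * config.background_rate for c in genome.names}
        total = sum(float(intensity[c].sum()) for c in genome.names)
        return {c: intensity[c] * (depth / total) for c in genome.names}

    samples: dict[str, ReadSet] = {}
    for label in SAMPLE_LABELS:
        cond = 1 if label.endswith("cond1") else 2
        if label.startswith("input"):
            intensity = base
            depth = config.input_depth
        else:
            ff = fold_factors(cond)
            intensity = {c: base[c] * ff[c] for c in genome.names}
            depth = config.chip_depth
        samples[label] = _draw_reads(rng, genome, scaled_rates(intensity, depth), config, label)

    truth = GroundTruth(regions=regions, target_gene_ids=list(target_ids) + list(added_ids))
    return SimulationResult(genome=genome, genes=genes, samples=samples, truth=truth, config=config)


def write_fixture(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write chrom.sizes, refFlat, per-sample BED6 reads, truth TSV, config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "chrom.sizes"
    write_genome(result.genome, paths["genome"])
    paths["annotation"] = out / "genes.refflat"
    write_refflat(result.genes, paths["annotation"])
    for label, rs in result.samples.items():
        p = out / f"{label}.bed"
        write_bed6_reads(rs.reads, p)
        paths[label] = p
    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tstart\tend\tfold\tgene_id\tcondition1\tcondition2\n")
        for r in result.truth.regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.fold:g}\t{r.gene_id}\t"
                f"{int(r.in_condition1)}\t{int(r.in_condition2)}\n"
            )
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(result.config), fh, sort_keys=False)
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    regions = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            c, s0, e, f, gid, c1, c2 = line.split()
            regions.append(
                SpikeRegion(c, int(s0), int(e), float(f), gid, bool(int(c1)), bool(int(c2)))
            )
    return GroundTruth(regions=regions, target_gene_ids=[r.gene_id for r in regions])


def peak_truth_fdr(peaks: PeakSet, truth: GroundTruth, condition: int = 1) -> float:
    """Fraction of called peaks not overlapping any spiked region."""
    if len(peaks) == 0:
        return 0.0
    regions = truth.regions_in(condition)
    false = sum(
        not any(p.overlaps(r.chrom, r.start, r.end) for r in regions) for p in peaks
    )
    return false / len(peaks)


def spike_recovery(peaks: PeakSet, truth: GroundTruth, condition: int = 1) -> float:
    """Fraction of spiked regions overlapped by at least one called peak."""
    regions = truth.regions_in(condition)
    if not regions:
        return float("nan")
    hit = sum(
        any(p.overlaps(r.chrom, r.start, r.end) for p in peaks) for r in regions
    )
    return hit / len(regions)
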
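# Methods

## Model and procedure

`chipwin` implements a fixed-grid enrichment test for single-end ChIP-seq
against a matched input (non-immunoprecipitated chromatin) control.

**Read reduction.** Alignments are filtered to uniquely mapping reads
with at most 2 mismatches (reads with no recorded mismatch count pass
vacuously; for SAM without an explicit multi-hit tag, MAPQ ≥ 1 is the
documented uniqueness proxy). At most one read is counted per
(chromosome, 5' position, strand) key — the key includes strand so that
bidirectional fragment evidence at one position is preserved. Each
retained read is reduced to one counting position: its 5' end shifted
`shift` bp in the 3' direction, default 150 bp, half the 300-bp midpoint
of a 200–500 bp sonication range, so counts approximate fragment
midpoints. Whether the original analyses of this data class counted 5'
ends, midpoints or extended fragments is generally unreported; the shift
is therefore an explicit parameter, and `shift=0` recovers pure 5'-end
counting.

**Windowing.** Each chromosome is tiled with non-overlapping 100-bp
half-open windows; the final partial window is retained, so window
counts always sum to the library size (a tested invariant).

**Per-window test.** For window *w*, the ChIP count is tested one-sided
against a Poisson expectation

    lambda_w = max( i_w * N_chip/N_input,  N_chip * s / G,  lambda_floor )

with `lambda_floor = 0.25` reads/window. The depth scaling makes the
test invariant to sequencing depth imbalance; the genome-wide background
term and the floor guard against spuriously small expectations in
windows where the input happens to be empty — without them every stray
ChIP read over a zero-input window would be "infinitely" significant.
Significance is strict `p < alpha`, default `alpha = 1e-3`; a window
with zero ChIP reads has p = 1 by construction.

**Peak rule.** Maximal runs of at least `min_run = 2` consecutive
significant windows become peaks; isolated significant windows are
discarded. "Two neighbouring windows of the same significance" is read
as "a run of at least two windows each passing the cutoff", not as equal
p-values (the only coherent reading) and not as "flanked on both sides"
(that stricter variant is available as `rule="flanked"`). Each peak
records its window span, best p-value, and a summit — the midpoint of
its highest-ChIP-count window, first window winning ties.

**FDR.** The empirical FDR of a parameter setting is estimated by
swapping ChIP and input and re-calling at identical parameters:
FDR = (swapped peaks) / (forward peaks), capped at 1, reported 0 with a
zero-denominator flag when no forward peaks exist. Which empirical FDR
construction (swap, simulation, or BH) the classic analyses used is
typically unreported; the swap is self-contained and data-driven, and BH
q-values over window p-values are reported alongside as a cross-check.
On synthetic data with known truth, FDR is also measured directly as the
fraction of called peaks not overlapping any spiked region.

## Annotation layer

- **Gene binding:** a gene is bound when the gap between its TSS and the
  nearest peak interval is ≤ `tss_radius` (default 5000 bp, strict
  beyond). The binding call uses peak-edge-to-TSS distance (the most
  permissive reading of "peaks within 5 kb of the TSS"); histograms use
  summit-to-TSS, since a histogram needs a point statistic. Distances
  are signed in transcription direction, negative upstream.
- **Feature classes:** each peak is classified once, by its summit,
  into promoter / 5'UTR / 3'UTR / coding exon / intron / intergenic with
  that precedence when genes overlap (most promoter-like wins; among
  equal classes, annotation file order). The promoter is
  `promoter_up = 3000` bp upstream to `promoter_down = 0` bp downstream
  of the TSS — the customary upstream-3kb convention; published promoter
  fractions rarely state their extent, so both bounds are configurable.
  Exons of models without a CDS are classified as coding exon. The
  input-like baseline classifies uniformly sampled windows (seeded).
- **Chromosome enrichment:** per chromosome, a two-sided binomial test
  of observed peak count against expectation proportional to chromosome
  length. Length-proportional (rather than mappable-window-proportional)
  expectation is the simplest defensible null and a documented
  limitation.

## Profiles

Signal is window counts per million mapped reads, resampled onto a
relative grid (default ±5000 bp, 100-bp bins) around each anchor by
overlap fraction, treating counts as uniform within their window.
Minus-strand anchors are reversed so upstream is left. Anchors whose
flank crosses a chromosome edge are zero-padded and counted in
`n_edge_anchors`. Per-million units make profiles invariant under
library rescaling (tested). Two-condition comparisons report per-bin
difference and `log2((b+c)/(a+c))` with pseudocount `c = 0.5` RPM
(avoids division by zero in empty flanks), with 95% bands from a paired
anchor-level bootstrap (default 1000 resamples, seeded).

## qPCR arithmetic

Percent of input: `100 * 2^((Ct_input − log2(1/f)) − Ct_IP)` where `f`
is the input aliquot fraction — the aliquot's Ct is adjusted to a 100%
equivalent before comparison. The aliquot fraction is a required user
input. Relative expression: `2^(−ΔΔCt)` with a reference gene per
condition. Amplification efficiency is fixed at 2 (100%); no standard
curve calibration.

## Synthetic data generator

The generator emulates the statistical structure the test assumes, not
sequence-level detail:

- genome: 2 chromosomes × 1 Mb by default;
- 200 gene models, TSSs uniform with ≥ 2 kb spacing, random strand,
  3-exon structure with a CDS;
- input background: Poisson per window with a **smooth mean-one
  lognormal regional multiplier** (log-sd 0.2, Gaussian smoothing over
  20 windows) shared between ChIP and input. The shared field is what
  makes the per-window input term genuinely informative; with a flat
  background the input term would be vacuous against the genome-wide
  mean;
- ChIP spikes: 5-window (500 bp) regions centred on 10 target-gene
  TSSs at fold 10 over the local background;
- fragments 200–500 bp; each yields one 50-bp single-end read from a
  uniformly chosen end;
- depth: 100,000 reads per sample (≈5 reads per 100-bp window on the
  default genome — typical early-platform desk-scale coverage). Setting
  `background_rate` (reads/bp) explicitly overrides the depth target;
- a second condition removes (default) or adds spike regions, emulating
  a knockdown contrast; all four samples (chip/input × 2 conditions) are
  drawn independently;
- everything is deterministic under `seed`.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: mappability gaps and blacklist
artefacts, GC and fragmentation bias, copy-number variation,
overdispersion beyond the smooth regional field, broad-domain marks, and
duplicate structure from PCR (duplicates arise only by coincidental
position collision and are removed as in real processing).

## Numerical choices

- Poisson tails via `scipy.stats.poisson.sf(k-1, lambda)`; peak scores
  `−log10(min p)` cap p at 1e-300 to avoid −inf.
- Ties at `p == alpha` are excluded (strict inequality, as thresholds
  are conventionally printed).
- Summit ties broken by first (leftmost) window; deterministic outputs
  throughout — identical config and inputs reproduce byte-identical
  TSV/BED files (tested).
- Degenerate inputs are errors, not silent defaults: empty genome
  table, zero input library, per-million scaling of an empty library,
  empty anchor or peak sets, gene-set files matching nothing.
- Simulation sizes in the test-suite: unit tests run a scaled-down
  configuration (2 chromosomes of 200/100 kb, 40 genes, 30k reads) with
  the same structure; calibration, recovery and FDR checks run the full
  default configuration.

## Known limitations

- **Plug-in lambda is anti-conservative under strong regional
  variation.** The per-window expectation uses the window's own noisy
  input count; when the shared regional background varies strongly
  (lognormal log-sd ≳ 0.5 at ~5 reads/window), the realised null
  per-window false-positive rate can exceed the nominal alpha by a
  factor ≈2 at 1e-3. This is a property of the per-window-input design
  itself (the price of not borrowing strength across windows as
  multi-scale local-lambda callers do). At the default moderate regional
  variation the test is conservative, as discreteness dominates.
- One gene model per annotation record; no transcript collapsing.
- No paired-end support, GC correction, or broad-domain calling.
- Chromosome enrichment ignores mappability.
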
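# chipwin

Windowed-Poisson ChIP-seq peak calling against a matched input control,
with TSS-centric annotation, gene-set-anchored average profiling, and
ChIP-qPCR percent-of-input quantification.

`chipwin` is for analysts working with classic single-end ChIP-seq of
transcription-factor or histone-mark samples (e.g. a demethylase ChIP and
an H3K9me2 ChIP in control vs knockdown cells) who want a transparent,
fully reproducible implementation of the simplest defensible enrichment
test — fixed 100-bp windows and a per-window Poisson test against the
input — rather than a heavyweight caller. A seeded synthetic read
generator with known spiked ground truth makes every stage verifiable
without any external data.

## The statistic

The genome is tiled with non-overlapping 100-bp windows. For window *w*
with deduplicated ChIP count *k<sub>w</sub>* and input count
*i<sub>w</sub>*, the expectation is

```
lambda_w = max( i_w * N_chip / N_input ,  N_chip * s / G ,  lambda_floor )
```

(*N* = library sizes, *s* = window size, *G* = genome length,
`lambda_floor` = 0.25 reads/window), and the one-sided p-value is the
Poisson upper tail `P(X >= k_w | lambda_w)`. Windows with `p < 1e-3`
(strict) are significant; maximal runs of **two or more consecutive
significant windows** become peaks, isolated windows are discarded.
The empirical FDR of a setting is estimated by swapping ChIP and input
and re-calling at identical parameters; Benjamini–Hochberg q-values over
the window p-values are reported alongside.

Downstream: genes are called bound when a peak lies within 5 kb of
their TSS; peak summits are classified into
promoter / 5'UTR / coding exon / 3'UTR / intron / intergenic;
per-chromosome peak counts get a binomial enrichment test; and average
reads-per-million profiles are built on a ±5 kb grid around any anchor
set (all TSSs or a supplied gene list), with paired bootstrap bands for
two-condition comparisons.

## Worked example

```python
from chipwin import (SimulationConfig, simulate, count_windows,
                     PoissonWindowModel, assign_genes, spike_recovery)

sim = simulate(SimulationConfig(seed=1))          # 2x1 Mb genome, 200 genes,
                                                  # 10 spiked TSS regions, fold 10
chip = count_windows(sim.samples["chip_cond1"], sim.genome)
inp  = count_windows(sim.samples["input_cond1"], sim.genome)
results = PoissonWindowModel(chip, inp).fit()
print(results.summary())
bindings = assign_genes(results.peaks, sim.genes)
print(f"bound genes: {sum(b.bound for b in bindings)} / {len(bindings)}")
print(f"spike recovery: {spike_recovery(results.peaks, sim.truth):.2f}")
```

prints

```
Windowed-Poisson peak calling (ChIP vs input)
================================================
ChIP sample:          chip_cond1
Input sample:         input_cond1
ChIP library size:    98257
Input library size:   98940
Window size:          100 bp
Windows tested:       20000
alpha (per window):   0.001  (strict p < alpha)
Peak rule:            run, min run 2
Significant windows:  70
  of which BH q<0.05: 57
Peaks called:         10
Swap FDR estimate:    0.0000 [0/10]
bound genes: 17 / 200
spike recovery: 1.00
```

All 10 spiked regions are recovered as peaks, no background peak is
called (swap FDR 0), and the 17 bound genes are the 10 targets plus
neighbours whose TSSs fall within 5 kb of a peak.

The same pipeline runs from the shell:

```sh
chipwin simulate --seed 1 --out fixture/
chipwin callpeaks --genome fixture/chrom.sizes \
    --chip fixture/chip_cond1.bed --input fixture/input_cond1.bed \
    --out peaks.bed
chipwin run --config run.yaml        # composite: count, call, annotate, profile
```

Real data enters the same way: SAM alignments or BED6 read placements
plus a chrom.sizes table and a refFlat/BED12 annotation.

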
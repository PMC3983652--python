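# h3turnover

Quantify **replication-independent nucleosome turnover** of the histone
variant H3.3 from induction time-course ChIP-seq.

When an epitope-tagged H3.3 is switched on (e.g. by doxycycline) in
arrested cells, its genome-wide incorporation over the following hours
reports where nucleosomes exchange outside of DNA replication: fast at
promoters and enhancers, at an intermediate rate over transcribed gene
bodies, slowly at telomeres, and not at all at pericentromeric
heterochromatin. `h3turnover` implements the full analysis for such an
experiment, plus a synthetic-data generator with known kinetics so every
stage can be validated end to end against ground truth.

## The model

For each peak called at the final induction time point, relative
enrichment is the depth-normalized ChIP count over the depth-normalized
input count, giving a series E_0, E_1, …, E_n over the ordered time
points. The **turnover index (TI)** is the slope of the linear model

```
E_t = TI · t + E_0 ,   t = 0, 1, 2, …, n  (time-point index)
```

With fixed sequencing depth, peaks that saturate early lose read share
to late-appearing peaks and their enrichment declines after its maximum.
The fit is therefore truncated: for a peak whose maximum lies at index
*m* < *n*, ordinary least squares is run over points 0…e for every
candidate end e in [m, n] and the fit with the smallest slope *P*-value
is adopted. Indices are min–max scaled to [0, 1] (optionally on a log
scale) for comparisons across experiments.

Around this core the package provides:

- **Island peak calling** — fixed 200-bp windows, Poisson eligibility,
  600-bp gap linking, island-level Poisson test against the input with
  Benjamini–Hochberg FDR 0.01 (`h3turnover.islands`);
- **Genomic-category analyses** — a strand-aware
  promoter / 5'UTR / exon / 3'UTR / intron / TES / intergenic partition,
  peak-center annotation, length-normalized category enrichment, the
  10 %-of-the-shorter-peak overlap rule, and repeat-class (telomere,
  pericentromere, tRNA, rRNA, …) enrichment time courses
  (`h3turnover.annotate`);
- **Metagene profiles** — TSS−3 kb → TSS → body (100 windows of 1 % gene
  length) → TES → TES+5 kb, stratified by RPKM quintiles
  (`h3turnover.metagene`);
- **Mark association** — peaks × marks presence/level matrix, quartile
  bin means, combinatorial presence-pattern group comparisons with
  rank-sum tests, TI-sorted heatmap tables (`h3turnover.marks`);
- **Synthetic data** — a small two-chromosome genome whose deposition
  sites follow first-order exchange occ(t) = A·(1 − e^(−kt)) in three
  ordered rate tiers, sampled into fixed-depth read libraries by
  multinomial allocation (which reproduces the read-share decline the
  truncated fit exists to handle), with coupled histone marks and
  expression (`h3turnover.simulate`).

## Worked example

```python
from scipy import stats
from h3turnover import SimConfig, run_analysis, simulate_dataset
from h3turnover.simulate import match_peaks_to_sites

ds = simulate_dataset(SimConfig(seed=1))          # 12 time points, 2e5 reads each
res = run_analysis(ds.chip_libs, ds.input_lib, ds.genome.genes,
                   ds.genome.chromosomes, ds.genome.repeat_blocks,
                   ds.mark_sets, ds.mark_libs, ds.rna_lib)

sites = match_peaks_to_sites(res.peak_universe, ds.genome.sites)
pairs = [(s.k, f.ti_scaled) for s, f in zip(sites, res.fits) if s is not None]
print(stats.spearmanr(*zip(*pairs)).statistic)
print(res.category_summary[["n", "mean_ti"]].round(3))
```

prints (seed 1):

```
0.869
             n  mean_ti
enhancer    83    0.125
gene_body  148    0.029
other        8    0.032
promoter   144    0.280
telomere    64    0.008
```

447 islands are called at 72 h; the scaled TI ranks the 445
truth-matched peaks by their true exchange-rate constant with Spearman
ρ = 0.87, and the mean TI ordering promoter > enhancer > gene body >
telomere reproduces the three-tier turnover hierarchy the method is
designed to detect. The scripts in `examples/` walk through each
capability (simulation, island calling, TI fitting, metagene timing,
mark association) and print what the numbers mean.

A thin CLI wraps the same stages for shell use:

```
h3turnover simulate --seed 1 --out data/
h3turnover callpeaks --chip data/chip_72h.bed --input data/input.bed \
    --chroms data/chromosomes.tsv --out peaks.tsv
h3turnover run --manifest manifest.tsv --chroms data/chromosomes.tsv \
    --genes data/genes.refflat --repeats data/repeats.bed --out results/
```

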
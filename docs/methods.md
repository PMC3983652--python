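# Methods

This note documents the models, estimators and design choices behind
`h3turnover`, in the spirit of a statistical-software methods appendix.

## The turnover index

The experiment this package analyses induces an epitope-tagged H3.3 in
replication-arrested cells and sequences ChIP libraries at 0, 1, 2, 3,
4, 5, 6, 12, 18, 24, 48 and 72 hours, plus an input control. All
quantification happens inside a single peak universe called on the final
(72 h) library, where both early- and late-appearing peaks are visible.

Per peak and time point, relative enrichment is

E_t = (peak tags / library total) / ((input peak tags + 1) / input total),

with tags counted at strand-shifted positions (default shift 75 b, half
a nominal 150-b fragment; the pseudocount guards zero-input peaks). The
turnover index is the slope of E_t = TI·t + E_0 fitted by ordinary least
squares, where t is by default the *time-point index* 0, 1, …, n rather
than hours — the printed form of the model — so the TI is invariant to
the uneven hour spacing. An `hours` axis is available as an option.

**Endpoint truncation.** Sequencing depth is fixed, so once a peak
saturates its read share is progressively diluted by late-appearing
signal and its E_t declines after the maximum. For a peak whose maximum
enrichment lies at index m < n, candidate fits over points 0…e are
computed for every end e in [m, n] and the one with the smallest
two-sided slope P-value is adopted (ties in the maximum resolve to the
earliest index, maximizing the search space; ties in P resolve to the
shortest fit). If the maximum is at the last point the single full fit
is used. The intercept is estimated, not pinned to the measured 0-h
enrichment. A constant response is reported as slope 0 with P = 1; an
exactly collinear one receives the smallest positive P representable.

TIs are min–max scaled to [0, 1] across the peak set (`linear` mode);
`log` mode applies the same min–max to log TI after clamping
non-positive slopes at one tenth of the smallest positive TI. Scaling
preserves ranks and maps the extremes to exactly 0 and 1.

**Estimator properties worth knowing.** For saturating (fast) peaks the
truncated slope behaves like amplitude ÷ argmax-index. Two consequences,
both visible in the validation suite: (i) within the fast class the TI
carries little information about the rate constant itself — the method's
power is in ordering the fast/intermediate/slow *tiers*, which is the
claim it supports; (ii) when the post-maximum decline is shallow, noise
moves the argmax along the plateau and inflates the TI's variance. At
the default desk-scale depth (2×10⁵ reads/library) this variance, plus
the per-peak input-normalization noise, caps the between-replicate
Pearson correlation of scaled TIs near 0.6 (Spearman ≈ 0.9); the Pearson
correlation reaches ≈ 0.85 only at around 10⁶ reads/library. The
acceptance script reports both so the depth dependence is explicit.

## Island peak calling

Broad H3.3 domains are found with a cluster-based island caller: the
genome is tiled into 200-bp windows; a window is eligible when its tag
count reaches the smallest integer whose upper-tail probability under
Poisson(λ) falls below 0.2, with λ the genome-wide rate
`library total × window / (effective fraction × genome length)`;
eligible windows link into maximal islands whenever the intervening
ineligible stretch is at most 600 bp. Island score is Σ −log
Poisson(count; λ) over eligible windows. Each island is then tested
against the input: its expected count is the island's input count scaled
by the depth ratio, *floored at the input's genome-wide uniform
expectation for the island's length* (and at a pseudocount of 1), and
the Poisson upper-tail p-values are Benjamini–Hochberg adjusted with
islands above FDR 0.01 removed. The floor matters: without it, 200-bp
islands whose sparse input happens to hold zero reads receive near-zero
expectations and background fluctuations flood the peak universe. On
planted-island benchmarks the caller reaches recall 1.0 and precision
≥ 0.95 at the default parameters.

## Genomic categories, overlap rule, repeats

Every genomic position receives exactly one category by precedence
promoter > 5'UTR > exon > 3'UTR > intron > TES region > intergenic, with
the promoter defined as 3 kb upstream of the TSS and the TES region as
TES to +5 kb, strand-aware; the partition is implemented as per-chromosome
label arrays (a pointwise minimum over category codes), so category base
totals always sum exactly to the genome length. Peaks are annotated by
their center (midpoint, floor division). Category enrichment divides
length-normalized, depth-normalized ChIP density by input density.

Two peaks overlap when the shared span covers ≥ 10 % of the *shorter*
peak — the shorter-peak denominator makes the relation symmetric.
Repeat-class enrichment is the ratio of ChIP to input read proportions
over annotated repeat blocks (pseudocount 1 on the input count). For
turnover summaries, peaks are labelled telomere (overlapping a telomeric
block), promoter (center in promoter/5'UTR), enhancer (intergenic center
≥ 1 kb from any TSS, or wholly intronic, carrying ≥ 1 of H3K4me1 /
H3K27ac / H2A.Z under the overlap rule; the mark requirement can be
dropped when the analysis itself stratifies by marks), gene body
(center in exon/intron/3'UTR), or TES.

## Metagene profiles

Profiles cover TSS−3 kb → TSS in 60 windows of 50 bp, the gene body in
100 windows each 1 % of gene length, and TES → TES+5 kb in 100 windows
of 50 bp, mirrored on the minus strand. Window density is count /
window bases / (normalizing total in millions); when peak filtering is
on, only reads inside the called peak universe count and the normalizing
total is the peak-filtered read count (the same interpretation is
applied to every ChIP library; the input library is not involved in
profile normalization). Genes are averaged within expression groups:
five equal-count RPKM quintiles (ties broken deterministically by gene
name), with RPKM < 1 separately flagged inactive. RPKM is exonic reads /
(exonic kb × library millions). Genes shorter than 100 b (configurable)
are excluded with a warning. Overlapping genes are profiled
independently; a read may contribute to more than one gene.

## Bimodality and mark association

The fast/slow split of the TI distribution is a two-component Gaussian
mixture, by default on the log-scaled TI (the log symmetrizes the
multiplicative spread of slopes). Two populations are reported when the
two-component model is preferred by BIC *and* neither component is an
outlier sink: a component holding fewer than five peaks triggers the
single-population fallback, as does an empty component or a degenerate
distribution. Component covariances are regularized at 10⁻⁴ of the data
variance to prevent razor-thin components gluing onto single outliers.
Labels follow the posterior at 0.5; the reported threshold is the TI
where the posteriors cross.

Mark analysis builds a peaks × marks matrix: presence via the overlap
rule against mark peak sets, level as mark tags per million per kb
within the H3.3 peak. Level-quartile bins (equal-count; equal-width
available) report mean TI per bin. Combinatorial groups over the five
active marks (H3K4me1, H3K4me3, H3K9ac, H3K27ac, H2A.Z) — all five
present, missing exactly one, none, exactly one, all five without
repressive marks, and all five plus H3K27me3 / H3K36me3 / both — are
compared to their family reference with two-sided Mann–Whitney tests;
Benjamini–Hochberg q-values are reported per family alongside raw P.
Under simulated independence of marks and turnover the fraction of
rank-sum tests below 0.05 stays near the nominal level (measured ≈ 0.02
across 200 synthetic datasets).

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions
under which the estimators are validated.

**Genome.** Two 5-Mb chromosomes with telomeric blocks at the ends, a
pericentromeric block in the middle, and genes, intergenic enhancers and
tRNA/rRNA/LINE/SINE/satellite repeat blocks dealt onto the arms with
randomized spacing (≥ ~2 kb between deposition sites, so neighbouring
sites resolve as separate islands). Genes carry exon/intron structure,
fixed-length UTRs and a strand.

**Kinetics.** Each deposition site follows first-order exchange
occ(t) = A·(1 − e^(−kt)). The linear TI is the *estimator*, not the
generative truth — the validation asks whether the paper-style linear
index ranks sites by the true k. Default rate tiers (per hour): fast
0.5–1.5 (promoters of expressed genes, most enhancers, tRNA blocks),
intermediate 0.02–0.04 (gene bodies of expressed genes, rRNA blocks),
slow 0.004–0.007 (telomeric sites and a 25 % minority of enhancers —
the broad enhancer turnover range seen in this system), and no
deposition at pericentromeres. Intermediate rates put gene-body onset
after the 6 h library and keep bodies rising to 72 h; slow rates make
telomeric enrichment detectable only from ~48 h.

**Amplitudes.** Site amplitude is a class scale (promoter 2.0, enhancer
0.9, gene body 0.7, telomere 1.1, tRNA 1.2, rRNA 0.6) times a ±10 %
jitter, times couplings: gene-body amplitude grows monotonically with
the gene's latent expression; enhancer amplitude is multiplied by
(base + step × number of active marks present) and shrunk by H3K27me3
and H3K36me3 — histone-mark content determining local nucleosome
stability is precisely the hypothesis the mark analyses probe, so the
generator encodes it. The telomeric scale sits above gene bodies so
slow sites still clear the island-eligibility threshold at 72 h while
their slopes stay the lowest (occupancy at 72 h is far below A).

**Read sampling.** Each ChIP library holds exactly `depth_per_library`
reads (default 2×10⁵) allocated multinomially with site weight
occ(t) × site length plus a fixed uniform-background weight chosen so
the background share equals `background_fraction` (default 0.5) at full
saturation; read centers are uniform within the chosen site and tag
positions are the strand-shifted 5' ends. The input library is
background-only at the same depth. Fixed-depth allocation — rather than
independent Poisson counts — is what mechanistically produces the
read-share decline of early-saturating peaks. Mark libraries weight
sites by a graded chromatin-state score (presence boost × a continuous
local-turnover score, inverted for repressive marks), so mark levels
track turnover smoothly rather than as an on/off track. RNA reads fall
only in exons, multinomially by expression × exonic length.

**Canned experiment designs** (factory functions in
`h3turnover.simulate`): `two_class_config` / `single_class_config` for
the bimodality analysis (enhancer-only genomes; the fast range 0.25–0.4/h
lets enrichment rise smoothly into the 12 h point, pinning the
truncation argmax so each class's TI distribution is compact and
log-symmetric; the two-class design separates the rates by two orders of
magnitude); `mark_association_config` (a 30-Mb genome with 2000 2-kb
intergenic enhancers at 2×10⁶ reads/library, amplitude driven entirely
by mark content) for the combinatorial group comparisons;
`null_profile_config` (a dense 1.8-Mb genome of 240 short genes) for
metagene flatness under uniform reads; `planted_island_dataset` for
caller recall/precision; `uniform_library` for null enrichment ratios.
Scaled-down problem sizes throughout are a deliberate desk-scale choice:
large enough for stable statistics, small enough to run the whole
validation in minutes.

**What the generator does and does not emulate.** It reproduces the
statistical structure the analyses rely on: saturating kinetics in
ordered tiers, fixed-depth read-share competition, Poisson-like count
noise, mark–class and expression–amplitude coupling, interval-labelled
repeats. It does not model sequence content (no FASTQ or alignment;
reads are generated pre-mapped), mappability variation, fragment-length
distributions, replication-coupled deposition, cell-cycle heterogeneity,
or chromatin-state autocorrelation beyond the site level. Passing tests
therefore demonstrate correctness of the estimators under these idealized
conditions, not robustness to alignment artifacts or copy-number
structure in real libraries.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open everywhere internally; refFlat-style
  tables convert on read. Adjacent intervals never double-count a tag.
- Duplicate removal keys on (chromosome, position, strand).
- All randomness flows through numpy Generators seeded from a single
  config seed with fixed stream offsets per stage, so identical configs
  give bit-identical outputs.
- Degenerate cases raise informative errors rather than guessing: empty
  input library, zero allocation weights at t = 0 with no background,
  constant predictors, series shorter than three points, all-equal TIs
  at scaling, fewer than ten shared peaks at concordance, fewer than 50
  fits at mixture classification.

## Known limitations

- The replicate-concordance Pearson correlation of scaled TIs is
  depth-limited (see the estimator-properties paragraph); comparisons of
  TI magnitudes across shallow replicates should prefer rank statistics.
- Within the fast tier the ordinal-axis TI is nearly amplitude-driven;
  it should not be read as a rate constant.
- The island caller is a simplified cluster caller, not a re-implementation
  of any published tool's exact statistics; parameters (window 200 bp,
  gap 600 bp, FDR 0.01, eligibility 0.2) are exposed on `IslandParams`.
- Real-data use requires a pre-computed repeat BED (e.g.
  RepeatMasker-derived) and refFlat-style gene models; no liftover, no
  BAM input (convert to BED tags first).
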
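"""Synthetic genome and time-course ChIP-seq generator with known turnover kinetics.

The generator builds a small two-chromosome genome carrying promoters,
enhancers, gene bodies, telomeric/pericentromeric blocks and tRNA/rRNA
repeats, assigns each H3.3 deposition site a first-order exchange model
occ(t) = A * (1 - exp(-k t)), and samples fixed-depth read libraries by
multinomial allocation.  Fixed depth is deliberate: as late-saturating
sites accumulate signal they draw read share away from early-saturating
ones, reproducing the apparent post-maximum decline of fast peaks that the
downstream truncated-regression estimator has to cope with.

Kinetic classes (true rate constants ordered fast > intermediate > slow):

======================  ==========================  =========================
class                   placement                   kinetics
======================  ==========================  =========================
promoter_fast           1 kb upstream of active TSS fast
enhancer_fast           intergenic 600 bp elements  fast
enhancer_slow           intergenic 600 bp elements  slow (minority fraction)
genebody_intermediate   interior of active genes    intermediate
telomere_slow           terminal repeat blocks      slow
pericentromere_none     interior repeat blocks      no deposition
trna_fast               tRNA repeat blocks          fast
rrna_intermediate       rRNA repeat blocks          intermediate
======================  ==========================  =========================
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic import GeneModel, GenomicInterval, TagLibrary, write_bed, write_refflat, write_tag_bed

ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H2A.Z")
REPRESSIVE_MARKS = ("H3K27me3", "H3K36me3", "H3K9me2")
ALL_MARKS = ACTIVE_MARKS + REPRESSIVE_MARKS

SITE_CLASSES = (
    "promoter_fast",
    "enhancer_fast",
    "enhancer_slow",
    "genebody_intermediate",
    "telomere_slow",
    "pericentromere_none",
    "trna_fast",
    "rrna_intermediate",
)

#: default per-mark, per-class assignment probability
DEFAULT_MARK_COUPLING: dict[str, dict[str, float]] = {}
for _m in ACTIVE_MARKS:
    DEFAULT_MARK_COUPLING[_m] = {
        "promoter_fast": 0.90, "enhancer_fast": 0.85, "enhancer_slow": 0.15,
        "genebody_intermediate": 0.05, "telomere_slow": 0.05,
        "trna_fast": 0.60, "rrna_intermediate": 0.30,
    }
DEFAULT_MARK_COUPLING["H3K27me3"] = {
    "promoter_fast": 0.05, "enhancer_fast": 0.15, "enhancer_slow": 0.80,
    "genebody_intermediate": 0.15, "telomere_slow": 0.70,
    "trna_fast": 0.02, "rrna_intermediate": 0.10,
}
DEFAULT_MARK_COUPLING["H3K36me3"] = {
    "promoter_fast": 0.05, "enhancer_fast": 0.08, "enhancer_slow": 0.30,
    "genebody_intermediate": 0.90, "telomere_slow": 0.05,
    "trna_fast": 0.02, "rrna_intermediate": 0.10,
}
DEFAULT_MARK_COUPLING["H3K9me2"] = {
    "promoter_fast": 0.02, "enhancer_fast": 0.05, "enhancer_slow": 0.30,
    "genebody_intermediate": 0.05, "telomere_slow": 0.80,
    "trna_fast": 0.02, "rrna_intermediate": 0.05,
}

#: per-class mean saturation amplitude (dimensionless occupancy scale)
CLASS_AMPLITUDE = {
    "promoter_fast": 2.0,
    "enhancer_fast": 0.9,
    "enhancer_slow": 0.9,
    "genebody_intermediate": 0.7,
    # telomeric amplitude sits above gene bodies so that slow sites still
    # clear the island-calling threshold at 72 h despite occ(72) << A;
    # their fitted slopes remain the lowest because occupancy rises slowly
    "telomere_slow": 1.1,
    "trna_fast": 1.2,
    "rrna_intermediate": 0.6,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic time course.

    Defaults emulate the real experiment's design: 12 induction time points
    over 0-72 h, ~500 deposition sites in three ordered kinetic tiers, fixed
    per-library depth of 2e5 reads, and a uniform non-site background that
    also serves as the input library model.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    n_genes: int = 180
    n_enhancers: int = 80
    n_trna: int = 16
    n_rrna: int = 16
    n_line: int = 30
    n_sine: int = 40
    n_satellite: int = 15
    enhancer_length: int = 600
    placement_margin: int = 4_000
    placement_gap: tuple[int, int] = (2_000, 6_000)
    time_points_h: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 12, 18, 24, 48, 72)
    depth_per_library: int = 200_000
    read_length: int = 50
    shift: int = 75
    rate_fast: tuple[float, float] = (0.5, 1.5)          # per hour
    rate_intermediate: tuple[float, float] = (0.02, 0.04)
    rate_slow: tuple[float, float] = (0.004, 0.007)
    amplitude_range: tuple[float, float] = (0.9, 1.1)    # per-site jitter
    background_fraction: float = 0.5
    enhancer_slow_fraction: float = 0.25
    inactive_gene_fraction: float = 0.2
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    utr5_length: int = 500
    utr3_length: int = 600
    telomere_length: int = 88_000
    pericentromere_length: int = 60_000
    sites_per_telomere: int = 16
    rna_depth: int = 500_000
    mark_depth: int = 200_000
    mark_background_fraction: float = 0.3
    mark_coupling: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MARK_COUPLING.items()})
    #: amplitude multipliers applied to enhancer sites from assigned marks
    mark_amplitude_base: float = 0.45
    mark_amplitude_per_active: float = 0.11
    mark_amplitude_h3k27me3: float = 0.70
    mark_amplitude_h3k36me3: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        tp = self.time_points_h
        if len(tp) < 3 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_h must start at 0 and be strictly increasing")
        for name in ("rate_fast", "rate_intermediate", "rate_slow"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not (self.rate_fast[0] > self.rate_intermediate[1] > 0
                and self.rate_intermediate[0] > self.rate_slow[1] > 0):
            raise ValueError("rate ranges must satisfy fast > intermediate > slow")
        if self.depth_per_library <= 0:
            raise ValueError("depth_per_library must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        for m in self.mark_coupling:
            if m not in ALL_MARKS:
                raise ValueError(f"unknown mark name in coupling map: {m}")

    def hours(self) -> list[float]:
        return list(self.time_points_h)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["time_points_h"] = list(d["time_points_h"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("time_points_h", "rate_fast", "rate_intermediate", "rate_slow",
                    "amplitude_range", "gene_length_range", "placement_gap"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SiteTruth:
    """Ground truth for one deposition site."""

    site: GenomicInterval
    klass: str
    k: float            # per-hour exchange rate constant
    A: float            # saturation amplitude (dimensionless occupancy)
    name: str = ""
    gene: str | None = None
    marks: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.klass not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.klass}")
        if self.klass != "pericentromere_none" and self.k <= 0:
            raise ValueError("rate constant must be > 0")


@dataclass
class GenomeModel:
    chromosomes: dict[str, int]
    genes: list[GeneModel]
    enhancers: list[GenomicInterval]
    repeat_blocks: list[tuple[GenomicInterval, str]]
    sites: list[SiteTruth]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name, "chrom": s.site.chrom, "start": s.site.start,
                "end": s.site.end, "class": s.klass, "k": s.k, "A": s.A,
                "gene": s.gene or "", "marks": ",".join(sorted(s.marks)),
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows)

    def serialize(self) -> str:
        """Stable textual form of the genome model (determinism checks)."""
        payload = {
            "chromosomes": self.chromosomes,
            "genes": [
                [g.name, g.chrom, g.strand, g.tss, g.tes, g.cds_start, g.cds_end,
                 [[e.start, e.end] for e in g.exons],
                 None if g.expression is None else round(g.expression, 9)]
                for g in self.genes
            ],
            "enhancers": [[e.chrom, e.start, e.end, e.name] for e in self.enhancers],
            "repeats": [[b.chrom, b.start, b.end, c] for b, c in self.repeat_blocks],
            "sites": [
                [s.name, s.site.chrom, s.site.start, s.site.end, s.klass,
                 round(s.k, 12), round(s.A, 12), sorted(s.marks)]
                for s in self.sites
            ],
        }
        return json.dumps(payload, sort_keys=True)


class PlacementError(ValueError):
    """Raised when the genome is too small to place a requested feature."""


def expected_occupancy(truth: SiteTruth, t: float) -> float:
    """Expected dimensionless occupancy A * (1 - exp(-k t)) at time t hours."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if truth.klass == "pericentromere_none":
        return 0.0
    return truth.A * -math.expm1(-truth.k * t)


def _draw(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def _expression_amplitude_factor(expression: float) -> float:
    """Monotone coupling of gene-body amplitude to expression level."""
    return 0.85 + 0.3 * expression / (expression + 5.0)


def build_genome(config: SimConfig) -> GenomeModel:
    """Lay out chromosomes, genes, enhancers and repeat blocks; assign kinetics.

    Deterministic for a fixed ``config.seed``.  Features are shuffled and
    placed sequentially along the two chromosome arms with random spacers of
    at least 2 kb, which keeps neighbouring deposition sites far enough
    apart that the island caller resolves them as separate peaks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_chrom = config.n_chromosomes
    chrom_len = config.genome_length // n_chrom
    chromosomes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    names = list(chromosomes)

    genes: list[GeneModel] = []
    enhancers: list[GenomicInterval] = []
    repeat_blocks: list[tuple[GenomicInterval, str]] = []
    sites: list[SiteTruth] = []

    # terminal and pericentromeric repeat blocks
    tel = config.telomere_length
    peri = config.pericentromere_length
    for cname in names:
        L = chromosomes[cname]
        if 2 * tel + peri + 10_000 > L:
            raise PlacementError(f"chromosome {cname} too small for telomere/pericentromere blocks")
        repeat_blocks.append((GenomicInterval(cname, 0, tel, name="telomere"), "telomere"))
        repeat_blocks.append((GenomicInterval(cname, L - tel, L, name="telomere"), "telomere"))
        mid = L // 2
        repeat_blocks.append(
            (GenomicInterval(cname, mid - peri // 2, mid + peri // 2, name="pericentromere"),
             "pericentromere")
        )

    # telomeric slow sites: evenly spaced 4 kb sites inside each terminal block
    for block, klass in list(repeat_blocks):
        if klass != "telomere" or config.sites_per_telomere == 0:
            continue
        n = config.sites_per_telomere
        site_len = 4_000
        gap = (block.length - n * site_len) // (n + 1)
        if gap < 1_000:
            raise PlacementError("telomere block too small for requested sites")
        pos = block.start + gap
        for i in range(n):
            iv = GenomicInterval(block.chrom, pos, pos + site_len)
            sites.append(SiteTruth(
                iv, "telomere_slow", _draw(rng, config.rate_slow),
                CLASS_AMPLITUDE["telomere_slow"] * _draw(rng, config.amplitude_range),
                name=f"tel_{block.chrom}_{block.start}_{i}",
            ))
            pos += site_len + gap

    # feature roster: (kind, payload) shuffled and dealt onto the arms
    roster: list[tuple[str, int]] = []
    roster += [("gene", i) for i in range(config.n_genes)]
    roster += [("enhancer", i) for i in range(config.n_enhancers)]
    roster += [("trna", i) for i in range(config.n_trna)]
    roster += [("rrna", i) for i in range(config.n_rrna)]
    roster += [("LINE", i) for i in range(config.n_line)]
    roster += [("SINE", i) for i in range(config.n_sine)]
    roster += [("satellite", i) for i in range(config.n_satellite)]
    order = rng.permutation(len(roster))
    roster = [roster[i] for i in order]

    # gene latent attributes drawn up front (placement-independent)
    active = rng.random(config.n_genes) >= config.inactive_gene_fraction
    expression = np.where(active, rng.lognormal(mean=1.5, sigma=1.0, size=config.n_genes), 0.0)

    # free arms: [tel, mid-peri) and [mid+peri, L-tel) on each chromosome
    arms: list[tuple[str, int, int]] = []
    for cname in names:
        L = chromosomes[cname]
        mid = L // 2
        arms.append((cname, tel, mid - peri // 2))
        arms.append((cname, mid + peri // 2, L - tel))

    feature_len = {
        "trna": 4_000, "rrna": 8_000, "LINE": 4_000, "SINE": 3_000, "satellite": 6_000,
    }
    arm_idx = 0
    cname, cursor, arm_end = arms[0]

    def advance(length: int, what: str) -> tuple[str, int]:
        """Return (chrom, start) for a feature of `length`, moving the cursor."""
        nonlocal arm_idx, cname, cursor, arm_end
        margin = config.placement_margin  # room for promoters/flanks around genes
        while cursor + margin + length + margin > arm_end:
            arm_idx += 1
            if arm_idx >= len(arms):
                raise PlacementError(f"genome too small to place feature: {what}")
            cname, cursor, arm_end = arms[arm_idx]
        start = cursor + margin
        cursor = start + length + int(rng.integers(*config.placement_gap))
        return cname, start

    for kind, i in roster:
        if kind == "gene":
            g_len = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            chrom, start = advance(g_len, f"gene {i}")
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(rng, f"gene{i:04d}", chrom, start, g_len, strand, config)
            gene.expression = float(expression[i])
            genes.append(gene)
            if active[i]:
                q = _expression_amplitude_factor(gene.expression)
                # fast site in the proximal promoter
                if strand == "+":
                    prom = GenomicInterval(chrom, gene.tss - 1_200, gene.tss - 200)
                    body = GenomicInterval(chrom, gene.tss + 1_000, gene.tes - 800)
                else:
                    prom = GenomicInterval(chrom, gene.tss + 200, gene.tss + 1_200)
                    body = GenomicInterval(chrom, gene.tes + 800, gene.tss - 1_000)
                sites.append(SiteTruth(
                    prom, "promoter_fast", _draw(rng, config.rate_fast),
                    CLASS_AMPLITUDE["promoter_fast"] * _draw(rng, config.amplitude_range)
                    * (0.9 + 0.2 * gene.expression / (gene.expression + 5.0)),
                    name=f"prom_{gene.name}", gene=gene.name,
                ))
                sites.append(SiteTruth(
                    body, "genebody_intermediate", _draw(rng, config.rate_intermediate),
                    CLASS_AMPLITUDE["genebody_intermediate"] * _draw(rng, config.amplitude_range) * q,
                    name=f"body_{gene.name}", gene=gene.name,
                ))
        elif kind == "enhancer":
            e_len = config.enhancer_length
            chrom, start = advance(e_len, f"enhancer {i}")
            iv = GenomicInterval(chrom, start, start + e_len, name=f"enh{i:04d}")
            enhancers.append(iv)
            slow = rng.random() < config.enhancer_slow_fraction
            klass = "enhancer_slow" if slow else "enhancer_fast"
            rate = config.rate_slow if slow else config.rate_fast
            sites.append(SiteTruth(
                iv, klass, _draw(rng, rate),
                CLASS_AMPLITUDE[klass] * _draw(rng, config.amplitude_range),
                name=f"enh{i:04d}",
            ))
        else:
            length = feature_len[kind]
            chrom, start = advance(length, f"{kind} {i}")
            block = GenomicInterval(chrom, start, start + length, name=kind)
            repeat_blocks.append((block, kind))
            if kind == "trna":
                site = GenomicInterval(chrom, block.center - 500, block.center + 500)
                sites.append(SiteTruth(
                    site, "trna_fast", _draw(rng, config.rate_fast),
                    CLASS_AMPLITUDE["trna_fast"] * _draw(rng, config.amplitude_range),
                    name=f"trna{i:03d}",
                ))
            elif kind == "rrna":
                site = GenomicInterval(chrom, block.center - 1_000, block.center + 1_000)
                sites.append(SiteTruth(
                    site, "rrna_intermediate", _draw(rng, config.rate_intermediate),
                    CLASS_AMPLITUDE["rrna_intermediate"] * _draw(rng, config.amplitude_range),
                    name=f"rrna{i:03d}",
                ))

    return GenomeModel(chromosomes, genes, enhancers, repeat_blocks, sites)


def _make_gene(
    rng: np.random.Generator, name: str, chrom: str, start: int, length: int,
    strand: str, config: SimConfig,
) -> GeneModel:
    """Build an exon/intron structure with fixed-size terminal exons."""
    end = start + length
    first_len = max(800, config.utr5_length + 300)
    last_len = max(900, config.utr3_length + 300)
    n_mid = int(rng.integers(1, 7))
    interior = length - first_len - last_len
    # alternate intron/exon in the interior
    bounds = np.sort(rng.integers(500, interior - 500, size=2 * n_mid))
    exons = [GenomicInterval(chrom, start, start + first_len)]
    for j in range(n_mid):
        s = start + first_len + int(bounds[2 * j])
        e = start + first_len + int(bounds[2 * j + 1])
        if e - s >= 100 and s >= exons[-1].end + 200:
            exons.append(GenomicInterval(chrom, s, e))
    last = GenomicInterval(chrom, end - last_len, end)
    if last.start >= exons[-1].end + 200:
        exons.append(last)
    else:
        exons[-1] = GenomicInterval(chrom, exons[-1].start, end)
    if strand == "+":
        tss, tes = start, end
        cds_start, cds_end = start + config.utr5_length, end - config.utr3_length
    else:
        tss, tes = end, start
        cds_start, cds_end = start + config.utr3_length, end - config.utr5_length
    return GeneModel(name, chrom, strand, tss, tes, exons,
                     cds_start=cds_start, cds_end=cds_end)


# -- read sampling ------------------------------------------------------------


def _site_weights(genome: GenomeModel, t: float) -> np.ndarray:
    return np.array([expected_occupancy(s, t) * s.site.length for s in genome.sites])


def _background_weight(genome: GenomeModel, config: SimConfig) -> float:
    """Fixed background weight chosen so the background read share equals
    ``background_fraction`` when every site is saturated."""
    sat = sum(s.A * s.site.length for s in genome.sites)
    bf = config.background_fraction
    if sat == 0:
        return 1.0  # background-only genome
    return bf / (1.0 - bf) * sat


def _sample_uniform_genome(
    rng: np.random.Generator, genome: GenomeModel, n: int
) -> tuple[np.ndarray, np.ndarray]:
    names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in names], dtype=float)
    codes = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[codes]).astype(np.int64)
    return codes.astype(np.int32), pos


def _assemble_library(
    rng: np.random.Generator, genome: GenomeModel, config: SimConfig,
    site_counts: np.ndarray, n_background: int, label: str, hours: float,
) -> TagLibrary:
    names = list(genome.chromosomes)
    code_of = {c: i for i, c in enumerate(names)}
    chroms = []
    centers = []
    for s, n in zip(genome.sites, site_counts):
        if n == 0:
            continue
        chroms.append(np.full(n, code_of[s.site.chrom], dtype=np.int32))
        centers.append(s.site.start + (rng.random(n) * s.site.length).astype(np.int64))
    bg_codes, bg_pos = _sample_uniform_genome(rng, genome, n_background)
    chroms.append(bg_codes)
    centers.append(bg_pos)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=np.int32)
    center = np.concatenate(centers) if centers else np.array([], dtype=np.int64)
    strand = rng.integers(0, 2, size=len(center)).astype(np.int8)
    # tag position is the 5' read end; the strand-aware shift recovers the center
    pos = np.where(strand == 0, center - config.shift, center + config.shift)
    pos = np.clip(pos, 0, None)
    order = rng.permutation(len(pos))
    return TagLibrary(chrom[order], pos[order], strand[order],
                      label=label, hours=hours, chrom_names=names)


def simulate_timecourse(
    genome: GenomeModel, config: SimConfig, seed_offset: int = 0,
) -> tuple[list[TagLibrary], TagLibrary]:
    """Sample one ChIP library per time point plus a background-only input.

    Each library carries exactly ``depth_per_library`` reads, allocated
    multinomially between sites (weight occupancy x length) and a uniform
    background of fixed weight.  ``seed_offset`` selects an independent
    sampling replicate over the same genome truth.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 3, seed_offset))
    bg_w = _background_weight(genome, config)
    libs = []
    for ti, t in enumerate(config.time_points_h):
        w = np.append(_site_weights(genome, t), bg_w)
        if w.sum() <= 0:
            raise ValueError(
                "all allocation weights are zero; set background_fraction > 0 "
                "so the pre-induction library can be sampled"
            )
        counts = rng.multinomial(config.depth_per_library, w / w.sum())
        libs.append(_assemble_library(
            rng, genome, config, counts[:-1], int(counts[-1]),
            label=f"chip_{t:g}h", hours=float(t),
        ))
    input_lib = _assemble_library(
        rng, genome, config, np.zeros(len(genome.sites), dtype=int),
        config.depth_per_library, label="input", hours=0.0,
    )
    return libs, input_lib


# -- histone marks ------------------------------------------------------------


def simulate_marks(
    genome: GenomeModel, config: SimConfig,
) -> dict[str, list[GenomicInterval]]:
    """Assign histone marks to sites and modulate enhancer amplitudes.

    Assignment is Bernoulli per (mark, kinetic class) with the configured
    coupling probability; assignments are recorded on each SiteTruth.  The
    amplitude of enhancer sites is then scaled by the assigned marks
    (more active marks -> larger amplitude; H3K27me3/H3K36me3 shrink it),
    so the estimated turnover index co-varies with mark content within the
    enhancer compartment and not merely between kinetic classes.  Call this
    before :func:`simulate_timecourse`.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 2))
    mark_sets: dict[str, list[GenomicInterval]] = {m: [] for m in config.mark_coupling}
    for s in genome.sites:
        s.marks = set()
        for mark, coupling in config.mark_coupling.items():
            p = coupling.get(s.klass, 0.0)
            if rng.random() < p:
                s.marks.add(mark)
                mark_sets[mark].append(GenomicInterval(
                    s.site.chrom, max(0, s.site.start - 200), s.site.end + 200, name=mark,
                ))
        if s.klass in ("enhancer_fast", "enhancer_slow"):
            n_active = len(s.marks & set(ACTIVE_MARKS))
            factor = config.mark_amplitude_base + config.mark_amplitude_per_active * n_active
            if "H3K27me3" in s.marks:
                factor *= config.mark_amplitude_h3k27me3
            if "H3K36me3" in s.marks:
                factor *= config.mark_amplitude_h3k36me3
            s.A *= factor
    # off-site decoy mark intervals in intergenic space
    for mark in mark_sets:
        codes, pos = _sample_uniform_genome(rng, genome, 30)
        names = list(genome.chromosomes)
        for c, p in zip(codes, pos):
            p = int(min(p, genome.chromosomes[names[c]] - 1_001))
            mark_sets[mark].append(GenomicInterval(names[c], p, p + 1_000, name=mark))
    for mark in mark_sets:
        mark_sets[mark].sort()
    return mark_sets


def simulate_mark_libraries(
    genome: GenomeModel, config: SimConfig,
) -> dict[str, TagLibrary]:
    """Sample a read library per mark with continuous site-level intensities.

    The per-site weight combines presence of the mark with a smooth local
    turnover score (occupancy fraction reached by 6 h times the relative
    site amplitude), inverted for repressive marks.  Mark read density
    therefore varies continuously with local turnover even at sites where
    the mark was not called present, emulating the graded chromatin-state
    signal of real mark ChIP rather than an on/off track.
    """
    rng = np.random.default_rng((config.seed, 4))
    libs: dict[str, TagLibrary] = {}
    activity = np.array([-math.expm1(-6.0 * s.k) if s.klass != "pericentromere_none" else 0.0
                         for s in genome.sites])
    amps = np.array([s.A for s in genome.sites], dtype=float)
    rel_amp = amps / amps.max() if amps.size and amps.max() > 0 else amps
    turnover_score = activity * rel_amp
    lengths = np.array([s.site.length for s in genome.sites], dtype=float)
    for mark in config.mark_coupling:
        score = turnover_score if mark in ACTIVE_MARKS else 1.0 - 0.95 * turnover_score
        presence = np.array([mark in s.marks for s in genome.sites], dtype=float)
        # the graded chromatin-state score dominates; called mark peaks sit
        # on its upper tail rather than forming a separate on/off track
        w = lengths * (0.8 + 0.4 * presence) * np.maximum(score, 0.02)
        bg_frac = config.mark_background_fraction
        bg_w = bg_frac / (1 - bg_frac) * w.sum() if w.sum() > 0 else 1.0
        full = np.append(w, bg_w)
        counts = rng.multinomial(config.mark_depth, full / full.sum())
        libs[mark] = _assemble_library(
            rng, genome, config, counts[:-1], int(counts[-1]), label=mark, hours=0.0,
        )
    return libs


# -- expression ---------------------------------------------------------------


def simulate_expression(
    genome: GenomeModel, config: SimConfig,
) -> tuple[pd.DataFrame, TagLibrary]:
    """Sample an exon-restricted RNA library and tabulate per-gene RPKM.

    Reads are allocated multinomially across active genes with weight
    expression x exonic length and placed uniformly within exons, so RPKM
    recomputed from the library is proportional to the latent expression
    level.  Inactive genes receive no reads (RPKM 0 < 1 by construction).
    """
    rng = np.random.default_rng((config.seed, 5))
    genes = genome.genes
    for g in genes:
        if g.exonic_length == 0:
            raise ValueError(f"gene {g.name} has zero exonic length")
    expr = np.array([g.expression or 0.0 for g in genes])
    w = expr * np.array([g.exonic_length for g in genes], dtype=float)
    if w.sum() == 0:
        counts = np.zeros(len(genes), dtype=int)
    else:
        counts = rng.multinomial(config.rna_depth, w / w.sum())
    names = list(genome.chromosomes)
    code_of = {c: i for i, c in enumerate(names)}
    chroms, positions = [], []
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        ex_lens = np.array([e.length for e in g.exons], dtype=float)
        ex_idx = rng.choice(len(g.exons), size=n, p=ex_lens / ex_lens.sum())
        offs = (rng.random(n) * ex_lens[ex_idx]).astype(np.int64)
        starts = np.array([e.start for e in g.exons], dtype=np.int64)
        chroms.append(np.full(n, code_of[g.chrom], dtype=np.int32))
        positions.append(starts[ex_idx] + offs)
    if chroms:
        chrom = np.concatenate(chroms)
        pos = np.concatenate(positions)
    else:
        chrom = np.array([], dtype=np.int32)
        pos = np.array([], dtype=np.int64)
    strand = rng.integers(0, 2, size=len(pos)).astype(np.int8)
    rna = TagLibrary(chrom, pos, strand, label="rna", hours=0.0, chrom_names=names)
    total = max(len(rna), 1)
    rpkm = pd.DataFrame({
        "gene": [g.name for g in genes],
        "reads": counts,
        "exonic_kb": [g.exonic_length / 1e3 for g in genes],
    })
    rpkm["rpkm"] = rpkm["reads"] / (rpkm["exonic_kb"] * total / 1e6)
    for g, val in zip(genes, rpkm["rpkm"]):
        g.rpkm = float(val)
    return rpkm, rna


# -- canned experiment designs ------------------------------------------------


def two_class_config(seed: int = 0) -> SimConfig:
    """Enhancer-only genome with two well-separated kinetic classes.

    Half the enhancers exchange fast, half with a rate constant two orders
    of magnitude lower — the design for testing whether the TI
    distribution resolves two populations (the bimodality analysis).  The
    fast range is set so enrichment rises smoothly into the 12 h point,
    which pins the truncation argmax and keeps each class's TI
    distribution compact and log-symmetric.
    """
    return SimConfig(seed=seed, n_genes=0, n_enhancers=220, n_trna=0, n_rrna=0,
                     sites_per_telomere=0, enhancer_slow_fraction=0.5,
                     amplitude_range=(0.95, 1.05),
                     rate_fast=(0.25, 0.4), rate_slow=(0.001, 0.002))


def single_class_config(seed: int = 0) -> SimConfig:
    """Enhancer-only genome with a single (fast) kinetic class."""
    return SimConfig(seed=seed, n_genes=0, n_enhancers=220, n_trna=0, n_rrna=0,
                     sites_per_telomere=0, enhancer_slow_fraction=0.0,
                     amplitude_range=(0.95, 1.05), rate_fast=(0.25, 0.4))


def mark_association_config(seed: int = 0) -> SimConfig:
    """Enhancer-rich genome for mark-coupling analyses.

    All enhancers exchange fast so every presence-pattern group is
    callable; the H3.3 amplitude of each enhancer — and therefore its
    fitted turnover index — is driven by its mark content (more active
    marks raise it, H3K27me3/H3K36me3 lower it).  Marks are assigned
    independently per enhancer with moderate probabilities so the
    combinatorial groups (all five active, missing one, none, only one,
    with/without repressive marks) are all populated, and libraries are
    deep enough that per-peak slope noise does not drown the per-mark
    amplitude steps.
    """
    coupling = {m: dict(v) for m, v in DEFAULT_MARK_COUPLING.items()}
    for m in ACTIVE_MARKS:
        coupling[m]["enhancer_fast"] = 0.55
    coupling["H3K27me3"]["enhancer_fast"] = 0.15
    coupling["H3K36me3"]["enhancer_fast"] = 0.10
    coupling["H3K9me2"]["enhancer_fast"] = 0.05
    return SimConfig(seed=seed, genome_length=30_000_000, n_genes=200,
                     n_enhancers=2_000, n_trna=0, n_rrna=0,
                     sites_per_telomere=4, depth_per_library=2_000_000,
                     enhancer_length=2_000, enhancer_slow_fraction=0.0,
                     background_fraction=0.3, amplitude_range=(0.95, 1.05),
                     rate_fast=(0.25, 0.4),
                     mark_amplitude_base=0.0, mark_amplitude_per_active=0.20,
                     mark_amplitude_h3k27me3=0.60,
                     mark_coupling=coupling)


def null_profile_config(seed: int = 0) -> SimConfig:
    """Dense gene-rich genome for null (uniform-read) metagene flatness checks.

    Many short, tightly packed genes maximize per-window read counts at a
    fixed library depth, so a flat profile's sampling noise stays well
    inside a few percent of the window mean.
    """
    return SimConfig(seed=seed, genome_length=1_800_000, n_chromosomes=1,
                     n_genes=240, n_enhancers=0, n_trna=0, n_rrna=0, n_line=0,
                     n_sine=0, n_satellite=0, gene_length_range=(4_000, 5_000),
                     telomere_length=10_000, pericentromere_length=20_000,
                     sites_per_telomere=0, placement_margin=1_000,
                     placement_gap=(500, 1_500))


def uniform_library(
    genome: GenomeModel, config: SimConfig, depth: int, seed: int,
    label: str = "uniform", hours: float = 0.0,
) -> TagLibrary:
    """A library of uniformly placed reads (the null for enrichment ratios)."""
    rng = np.random.default_rng((seed, 7))
    return _assemble_library(rng, genome, config,
                             np.zeros(len(genome.sites), dtype=int), depth,
                             label=label, hours=hours)


def planted_island_dataset(
    seed: int = 0, genome_length: int = 5_000_000, n_islands: int = 60,
    background_depth: int = 100_000, island_reads: int = 400,
) -> tuple[TagLibrary, TagLibrary, dict[str, int], list[GenomicInterval]]:
    """ChIP/input pair with strong islands planted on a Poisson background.

    Returns (chip, input, chromosome lengths, planted intervals).  Islands
    are spaced far apart so the gap rule cannot merge distinct ones; each
    receives ``island_reads`` reads on top of the shared uniform background.
    """
    rng = np.random.default_rng((seed, 8))
    chrom = "chr1"
    spacing = genome_length // (n_islands + 1)
    planted = []
    for i in range(n_islands):
        length = int(rng.integers(1_000, 2_001))
        start = (i + 1) * spacing + int(rng.integers(0, spacing // 4))
        planted.append(GenomicInterval(chrom, start, start + length, name=f"island{i}"))

    def uniform_tags(n: int) -> tuple[np.ndarray, np.ndarray]:
        pos = rng.integers(0, genome_length, size=n).astype(np.int64)
        strand = rng.integers(0, 2, size=n).astype(np.int8)
        return pos, strand

    bg_pos, bg_strand = uniform_tags(background_depth)
    isl_pos, isl_strand = [], []
    for iv in planted:
        centers = iv.start + (rng.random(island_reads) * iv.length).astype(np.int64)
        strand = rng.integers(0, 2, size=island_reads).astype(np.int8)
        isl_pos.append(np.where(strand == 0, centers - 75, centers + 75))
        isl_strand.append(strand)
    chip_pos = np.concatenate([bg_pos] + isl_pos)
    chip_strand = np.concatenate([bg_strand] + isl_strand)
    chip = TagLibrary(np.zeros(len(chip_pos), dtype=np.int32), chip_pos, chip_strand,
                      label="chip", hours=72.0, chrom_names=[chrom])
    inp_pos, inp_strand = uniform_tags(background_depth + n_islands * island_reads)
    input_lib = TagLibrary(np.zeros(len(inp_pos), dtype=np.int32), inp_pos, inp_strand,
                           label="input", hours=0.0, chrom_names=[chrom])
    return chip, input_lib, {chrom: genome_length}, planted


def match_peaks_to_sites(
    peaks: list[GenomicInterval], sites: list[SiteTruth], min_frac: float = 0.5,
) -> list[SiteTruth | None]:
    """For each peak, the truth site it covers (>= min_frac of the site), or None.

    Evaluation utility for parameter-recovery analyses: peaks are matched
    to the deposition site they overlap best.
    """
    by_chrom: dict[str, list[SiteTruth]] = {}
    for s in sites:
        by_chrom.setdefault(s.site.chrom, []).append(s)
    out: list[SiteTruth | None] = []
    for p in peaks:
        best, best_ov = None, 0
        for s in by_chrom.get(p.chrom, []):
            ov = p.overlap(s.site)
            if ov > best_ov:
                best, best_ov = s, ov
        if best is not None and best_ov >= min_frac * best.site.length:
            out.append(best)
        else:
            out.append(None)
    return out


# -- dataset bundle -----------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: GenomeModel
    chip_libs: list[TagLibrary]
    input_lib: TagLibrary
    mark_sets: dict[str, list[GenomicInterval]]
    mark_libs: dict[str, TagLibrary]
    rpkm: pd.DataFrame
    rna_lib: TagLibrary


def simulate_dataset(config: SimConfig, with_marks: bool = True) -> SimulatedDataset:
    """Run the whole generator: genome, expression, marks, then read sampling."""
    genome = build_genome(config)
    rpkm, rna = simulate_expression(genome, config)
    if with_marks:
        mark_sets = simulate_marks(genome, config)
        mark_libs = simulate_mark_libraries(genome, config)
    else:
        mark_sets, mark_libs = {}, {}
    chip_libs, input_lib = simulate_timecourse(genome, config)
    return SimulatedDataset(config, genome, chip_libs, input_lib,
                            mark_sets, mark_libs, rpkm, rna)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset as plain-text files; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for lib in ds.chip_libs:
        p = outdir / f"chip_{lib.hours:g}h.bed"
        write_tag_bed(lib, p, ds.config.read_length)
        paths[lib.label] = str(p)
    write_tag_bed(ds.input_lib, outdir / "input.bed", ds.config.read_length)
    paths["input"] = str(outdir / "input.bed")
    write_refflat(ds.genome.genes, outdir / "genes.refflat")
    paths["genes"] = str(outdir / "genes.refflat")
    rep = [GenomicInterval(b.chrom, b.start, b.end, name=c) for b, c in ds.genome.repeat_blocks]
    write_bed(rep, outdir / "repeats.bed")
    paths["repeats"] = str(outdir / "repeats.bed")
    for mark, ivs in ds.mark_sets.items():
        p = outdir / f"mark_{mark.replace('.', '')}.bed"
        write_bed(ivs, p)
        paths[f"mark:{mark}"] = str(p)
    for mark, lib in ds.mark_libs.items():
        p = outdir / f"marklib_{mark.replace('.', '')}.bed"
        write_tag_bed(lib, p, ds.config.read_length)
        paths[f"marklib:{mark}"] = str(p)
    ds.rpkm.to_csv(outdir / "rpkm.tsv", sep="\t", index=False)
    paths["rpkm"] = str(outdir / "rpkm.tsv")
    ds.genome.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")
    ds.config.to_yaml(outdir / "config.yaml")
    paths["config"] = str(outdir / "config.yaml")
    with open(outdir / "chromosomes.tsv", "w") as fh:
        for c, L in ds.genome.chromosomes.items():
            fh.write(f"{c}\t{L}\n")
    paths["chromosomes"] = str(outdir / "chromosomes.tsv")
    return paths
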
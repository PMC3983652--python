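"""Genomic-category classification, peak annotation, and enrichment summaries.

The genome is partitioned into seven categories by precedence
(promoter > 5'UTR > exon > 3'UTR > intron > TES region > intergenic),
with the promoter defined as 3 kb upstream of the TSS and the TES region
as TES to 5 kb downstream, both strand-aware.  Every genomic position
receives exactly one category, so category base totals always sum to the
genome length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GeneModel, GenomicInterval, TagLibrary

CATEGORIES = ("promoter", "utr5", "exon", "utr3", "intron", "tes_region", "intergenic")
#: paint order: lowest precedence first so higher precedence overwrites
_PAINT_ORDER = ("tes_region", "intron", "utr3", "exon", "utr5", "promoter")
_CODE = {c: i for i, c in enumerate(CATEGORIES)}
_INTERGENIC = _CODE["intergenic"]


@dataclass
class CategorySchema:
    promoter_upstream: int = 3_000
    tes_downstream: int = 5_000


def _utr_and_coding_spans(gene: GeneModel) -> tuple[list, list, list]:
    """Split exons into (5'UTR, coding, 3'UTR) genomic spans by CDS bounds."""
    cds_s = gene.cds_start if gene.cds_start is not None else gene.start
    cds_e = gene.cds_end if gene.cds_end is not None else gene.end
    left, mid, right = [], [], []
    for ex in gene.exons:
        if ex.start < cds_s:
            left.append((ex.start, min(ex.end, cds_s)))
        if max(ex.start, cds_s) < min(ex.end, cds_e):
            mid.append((max(ex.start, cds_s), min(ex.end, cds_e)))
        if ex.end > cds_e:
            right.append((max(ex.start, cds_e), ex.end))
    if gene.strand == "+":
        return left, mid, right  # left of CDS = 5'UTR
    return right, mid, left


class CategoryMap:
    """Per-chromosome category label arrays for O(1) position classification."""

    def __init__(self, genes: list[GeneModel], chrom_lengths: dict[str, int],
                 schema: CategorySchema | None = None) -> None:
        self.schema = schema or CategorySchema()
        self.chrom_lengths = dict(chrom_lengths)
        self.arrays: dict[str, np.ndarray] = {
            c: np.full(L, _INTERGENIC, dtype=np.int8) for c, L in chrom_lengths.items()
        }
        # precedence painting is a pointwise minimum over category codes, so
        # the paint order across genes does not matter
        for g in genes:
            if g.chrom not in self.arrays:
                raise ValueError(f"gene {g.name} on unknown chromosome {g.chrom}")
            arr = self.arrays[g.chrom]
            L = len(arr)
            utr5, coding, utr3 = _utr_and_coding_spans(g)
            if g.strand == "+":
                prom = (g.tss - self.schema.promoter_upstream, g.tss)
                tes = (g.tes, g.tes + self.schema.tes_downstream)
            else:
                prom = (g.tss, g.tss + self.schema.promoter_upstream)
                tes = (g.tes - self.schema.tes_downstream, g.tes)
            paint = {
                "tes_region": [tes], "intron": [(g.start, g.end)], "utr3": utr3,
                "exon": coding, "utr5": utr5, "promoter": [prom],
            }
            for cat in _PAINT_ORDER:
                code = _CODE[cat]
                for s, e in paint[cat]:
                    s, e = max(0, s), min(L, e)
                    if s < e:
                        cur = arr[s:e]
                        cur[cur > code] = code  # smaller code = higher precedence

    def classify(self, chrom: str, pos: int) -> str:
        arr = self.arrays.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        return CATEGORIES[arr[pos]]

    def base_totals(self) -> pd.Series:
        totals = np.zeros(len(CATEGORIES), dtype=np.int64)
        for arr in self.arrays.values():
            totals += np.bincount(arr, minlength=len(CATEGORIES))
        return pd.Series(totals, index=CATEGORIES)

    def count_positions(self, lib: TagLibrary, shift: int = 75) -> pd.Series:
        """Reads per category by shifted position (out-of-bounds positions clipped)."""
        totals = np.zeros(len(CATEGORIES), dtype=np.int64)
        idx = lib.shifted_index(shift)
        for chrom, arr in self.arrays.items():
            pos = idx.get(chrom)
            if pos is None or len(pos) == 0:
                continue
            pos = np.clip(pos, 0, len(arr) - 1)
            totals += np.bincount(arr[pos], minlength=len(CATEGORIES))
        return pd.Series(totals, index=CATEGORIES)


def classify_position(
    pos: int, chrom: str, catmap: CategoryMap,
) -> str:
    """Category of a single genomic position (see :class:`CategoryMap`)."""
    return catmap.classify(chrom, pos)


def annotate_peak_centers(
    peaks: list[GenomicInterval], catmap: CategoryMap,
) -> Counter:
    """Category counts of peak center positions (midpoint, floor division)."""
    if not peaks:
        raise ValueError("no peaks to annotate")
    out: Counter = Counter()
    for p in peaks:
        arr = catmap.arrays[p.chrom]
        center = min(p.center, len(arr) - 1)
        out[CATEGORIES[arr[center]]] += 1
    return out


@dataclass
class CategoryEnrichment:
    category: str
    total_reads: int
    total_bases: int
    density: float        # reads per base per million mapped
    input_density: float
    ratio: float


def category_enrichment(
    lib: TagLibrary, input_lib: TagLibrary, catmap: CategoryMap, shift: int = 75,
) -> list[CategoryEnrichment]:
    """Length-normalized read density per category, as a ratio over input."""
    bases = catmap.base_totals()
    chip = catmap.count_positions(lib, shift)
    inp = catmap.count_positions(input_lib, shift)
    out = []
    for cat in CATEGORIES:
        if bases[cat] == 0:
            continue
        dens = chip[cat] / bases[cat] * 1e6 / lib.total_mapped
        idens = inp[cat] / bases[cat] * 1e6 / input_lib.total_mapped
        ratio = dens / idens if idens > 0 else float("nan")
        out.append(CategoryEnrichment(cat, int(chip[cat]), int(bases[cat]),
                                      dens, idens, ratio))
    return out


def overlap_peaks(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval], frac: float = 0.10,
) -> tuple[list[tuple[int, int]], int]:
    """Pairs (i, j) where a_i and b_j overlap by >= frac of the shorter peak.

    Returns the pair list and the number of a-peaks with at least one
    overlapping b-peak.  The shorter-peak denominator makes the relation
    symmetric.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    import bisect

    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, b in enumerate(set_b):
        by_chrom.setdefault(b.chrom, []).append((j, b))
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda t: t[1].start)
        starts[chrom] = [b.start for _, b in lst]
        max_len[chrom] = max(b.length for _, b in lst)
    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    for i, a in enumerate(set_a):
        cands = by_chrom.get(a.chrom)
        if not cands:
            continue
        lo = bisect.bisect_left(starts[a.chrom], a.start - max_len[a.chrom])
        for j, b in cands[lo:]:
            if b.start >= a.end:
                break
            ov = a.overlap(b)
            if ov >= frac * min(a.length, b.length):
                pairs.append((i, j))
                hit_a.add(i)
    return pairs, len(hit_a)


def repeat_enrichment(
    lib: TagLibrary, input_lib: TagLibrary,
    repeat_blocks: list[tuple[GenomicInterval, str]],
    shift: int = 75, input_pseudocount: float = 1.0,
) -> dict[str, float]:
    """Per repeat class: (ChIP read proportion) / (input read proportion).

    Classes absent from the annotation are simply not in the result
    (callers can distinguish missing from zero).
    """
    from .genomic import count_tags_many

    classes = sorted({c for _, c in repeat_blocks})
    out: dict[str, float] = {}
    for cls in classes:
        regions = [iv for iv, c in repeat_blocks if c == cls]
        chip = int(count_tags_many(lib, regions, shift).sum())
        inp = int(count_tags_many(input_lib, regions, shift).sum())
        chip_prop = chip / lib.total_mapped
        input_prop = (inp + input_pseudocount) / input_lib.total_mapped
        out[cls] = chip_prop / input_prop
    return out


def repeat_timecourse(
    libraries: list[TagLibrary], input_lib: TagLibrary,
    repeat_blocks: list[tuple[GenomicInterval, str]], shift: int = 75,
) -> pd.DataFrame:
    """Repeat-class x time matrix of input-normalized enrichment ratios."""
    if len(libraries) < 2:
        raise ValueError("need at least 2 time points")
    libs = sorted(libraries, key=lambda lb: lb.hours)
    rows = {}
    for lb in libs:
        rows[lb.hours] = repeat_enrichment(lb, input_lib, repeat_blocks, shift)
    return pd.DataFrame(rows)  # index = class, columns = hours


def category_turnover_summary(
    fits, peak_labels: list[str],
) -> pd.DataFrame:
    """Mean and median scaled TI per peak category label."""
    if len(fits) != len(peak_labels):
        raise ValueError("fits and labels must align")
    df = pd.DataFrame({
        "label": peak_labels,
        "ti": [f.ti_scaled for f in fits],
    })
    g = df.groupby("label")["ti"]
    return pd.DataFrame({"n": g.size(), "mean_ti": g.mean(), "median_ti": g.median()})


def classify_peak_regions(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    catmap: CategoryMap,
    mark_sets: dict[str, list[GenomicInterval]] | None = None,
    repeat_blocks: list[tuple[GenomicInterval, str]] | None = None,
    enhancer_marks: tuple[str, ...] = ("H3K4me1", "H3K27ac", "H2A.Z"),
    min_tss_distance: int = 1_000,
    overlap_frac: float = 0.10,
    require_marks: bool = True,
) -> list[str]:
    """Functional region label per peak for turnover summaries.

    Labels: ``telomere`` (overlaps a telomeric repeat block), ``promoter``
    (center in promoter or 5'UTR), ``enhancer`` (intergenic center at least
    1 kb from any TSS, or wholly intronic, and carrying at least one
    enhancer-associated mark under the overlap rule), ``gene_body`` (center
    in exon/intron/3'UTR), ``tes`` and ``other``.  With
    ``require_marks=False`` the enhancer label is positional only —
    appropriate when the analysis itself stratifies peaks by mark content.
    """
    mark_sets = mark_sets or {}
    enh_intervals: list[GenomicInterval] = []
    for m in enhancer_marks:
        enh_intervals += mark_sets.get(m, [])
    has_mark = [not require_marks] * len(peaks)
    if require_marks and enh_intervals:
        pairs, _ = overlap_peaks(peaks, enh_intervals, overlap_frac)
        for i, _ in pairs:
            has_mark[i] = True
    tel_blocks = [iv for iv, c in (repeat_blocks or []) if c == "telomere"]
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    introns = _intron_spans(genes)

    labels = []
    for i, p in enumerate(peaks):
        if any(p.overlap(t) > 0 for t in tel_blocks):
            labels.append("telomere")
            continue
        cat = catmap.classify(p.chrom, min(p.center, catmap.chrom_lengths[p.chrom] - 1))
        if cat in ("promoter", "utr5"):
            labels.append("promoter")
            continue
        tss = tss_by_chrom.get(p.chrom, np.array([]))
        if len(tss):
            k = np.searchsorted(tss, p.center)
            dists = [abs(p.center - tss[j]) for j in (k - 1, k) if 0 <= j < len(tss)]
            tss_dist = min(dists) if dists else np.inf
        else:
            tss_dist = np.inf
        intronic = any(
            iv.start <= p.start and p.end <= iv.end
            for iv in introns.get(p.chrom, []) if iv.start < p.end and iv.end > p.start
        )
        if has_mark[i] and ((cat == "intergenic" and tss_dist >= min_tss_distance) or intronic):
            labels.append("enhancer")
        elif cat in ("exon", "intron", "utr3"):
            labels.append("gene_body")
        elif cat == "tes_region":
            labels.append("tes")
        else:
            labels.append("other")
    return labels


def _intron_spans(genes: list[GeneModel]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        prev = None
        for ex in g.exons:
            if prev is not None and ex.start > prev:
                out.setdefault(g.chrom, []).append(GenomicInterval(g.chrom, prev, ex.start))
            prev = ex.end
    return out
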
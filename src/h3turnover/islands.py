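"""Island-style peak calling for broad histone-variant ChIP-seq domains.

The caller follows the window/gap/score skeleton of cluster-based island
finders: the genome is tiled into fixed windows (200 bp), windows whose tag
count beats a Poisson background eligibility threshold are linked into
islands whenever the ineligible stretch between them is at most the gap
(600 bp), and islands are finally tested against the input library with a
Poisson enrichment test and a Benjamini-Hochberg FDR cut (0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import GenomicInterval, TagLibrary, count_tags_many


@dataclass
class IslandParams:
    window: int = 200
    gap: int = 600
    window_p: float = 0.2     # Poisson upper-tail eligibility threshold
    island_fdr: float = 0.01
    effective_fraction: float = 1.0
    input_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.gap % self.window != 0:
            raise ValueError("gap must be a multiple of window")
        if not 0 < self.island_fdr < 1:
            raise ValueError("island_fdr must be in (0, 1)")
        if not 0 < self.effective_fraction <= 1:
            raise ValueError("effective_fraction must be in (0, 1]")


@dataclass
class Island:
    region: GenomicInterval
    chip_count: int
    score: float
    input_count: int = 0
    p_value: float = float("nan")
    q_value: float = float("nan")


def window_counts(
    lib: TagLibrary, chrom_lengths: dict[str, int], params: IslandParams,
    shift: int = 75,
) -> dict[str, np.ndarray]:
    """Tag counts (by shifted position) in non-overlapping genome windows."""
    idx = lib.shifted_index(shift)
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // params.window)  # ceil
        pos = idx.get(chrom)
        if pos is None or len(pos) == 0:
            out[chrom] = np.zeros(n_win, dtype=np.int64)
            continue
        valid = pos[(pos >= 0) & (pos < length)]
        out[chrom] = np.bincount(valid // params.window, minlength=n_win).astype(np.int64)
    return out


def eligibility_threshold(lam: float, window_p: float) -> int:
    """Smallest integer count whose Poisson(lam) upper-tail prob is < window_p."""
    if lam <= 0:
        raise ValueError("background rate must be > 0")
    c = int(stats.poisson.ppf(1 - window_p, lam))
    # sf(c - 1) = P(X >= c); walk up until strictly below the threshold
    while stats.poisson.sf(c - 1, lam) >= window_p:
        c += 1
    return c


def call_islands(
    counts: dict[str, np.ndarray], lib_total: int, params: IslandParams,
) -> list[Island]:
    """Link eligible windows into islands under the gap rule.

    A window is eligible iff its count reaches the Poisson eligibility
    threshold for the genome-wide background rate lambda =
    lib_total * window / (effective_fraction * genome_length).  Islands are
    maximal runs of eligible windows in which consecutive eligible windows
    are separated by at most gap bases of ineligible windows.  The island
    score sums -log Poisson(count; lambda) over its eligible windows; the
    reported chip_count covers every window in the island span.
    """
    genome_length = sum(len(a) for a in counts.values()) * params.window
    lam = lib_total * params.window / (params.effective_fraction * genome_length)
    if lam <= 0:
        raise ValueError("background rate is zero; empty library or genome")
    thresh = eligibility_threshold(lam, params.window_p)
    max_gap_windows = params.gap // params.window
    islands: list[Island] = []
    for chrom, vec in counts.items():
        eligible = np.flatnonzero(vec >= thresh)
        if len(eligible) == 0:
            continue
        # split where the ineligible stretch exceeds the gap
        breaks = np.flatnonzero(np.diff(eligible) > max_gap_windows + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(eligible) - 1]))
        for s, e in zip(starts, ends):
            w0, w1 = eligible[s], eligible[e]
            run = vec[w0:w1 + 1]
            elig_counts = run[run >= thresh]
            with np.errstate(divide="ignore"):
                score = float(-stats.poisson.logpmf(elig_counts, lam).sum())
            islands.append(Island(
                region=GenomicInterval(chrom, int(w0) * params.window,
                                       (int(w1) + 1) * params.window),
                chip_count=int(run.sum()),
                score=score,
            ))
    islands.sort(key=lambda isl: (isl.region.chrom, isl.region.start))
    return islands


def filter_islands(
    islands: list[Island], chip_lib: TagLibrary, input_lib: TagLibrary,
    params: IslandParams, shift: int = 75, genome_length: int | None = None,
) -> list[Island]:
    """Drop islands not significantly enriched over the input library.

    The island's expected count is its input count scaled by the library
    depth ratio; p is the Poisson upper tail of the observed ChIP count,
    q the Benjamini-Hochberg adjustment across islands, and islands with q
    above the FDR threshold are removed.  The input count is floored at
    the input's genome-wide uniform expectation for the island's length
    (and at the pseudocount): short islands where the sparse input happens
    to hold zero reads must not acquire a near-zero expectation.
    """
    if not islands:
        return []
    if input_lib.total_mapped <= 0:
        raise ValueError("input library is empty")
    regions = [isl.region for isl in islands]
    input_counts = count_tags_many(input_lib, regions, shift)
    scale = chip_lib.total_mapped / input_lib.total_mapped
    p_values = np.empty(len(islands))
    for i, isl in enumerate(islands):
        isl.input_count = int(input_counts[i])
        floor = params.input_pseudocount
        if genome_length:
            floor = max(floor, input_lib.total_mapped * isl.region.length / genome_length)
        expected = max(isl.input_count, floor) * scale
        p_values[i] = stats.poisson.sf(isl.chip_count - 1, expected)
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    kept = []
    for isl, p, q in zip(islands, p_values, q_values):
        isl.p_value = float(p)
        isl.q_value = float(q)
        if q <= params.island_fdr:
            kept.append(isl)
    return kept


def call_peaks(
    chip_lib: TagLibrary, input_lib: TagLibrary, chrom_lengths: dict[str, int],
    params: IslandParams | None = None, shift: int = 75,
) -> list[Island]:
    """Full island pipeline: window counts -> island linking -> input FDR filter."""
    params = params or IslandParams()
    counts = window_counts(chip_lib, chrom_lengths, params, shift)
    islands = call_islands(counts, chip_lib.total_mapped, params)
    return filter_islands(islands, chip_lib, input_lib, params, shift,
                          genome_length=sum(chrom_lengths.values()))


def write_islands(islands: list[Island], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tchip\tinput\tp\tq\n")
        for i, isl in enumerate(islands):
            r = isl.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tisland_{i}\t{isl.score:.3f}\t."
                f"\t{isl.chip_count}\t{isl.input_count}\t{isl.p_value:.3e}\t{isl.q_value:.3e}\n"
            )
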
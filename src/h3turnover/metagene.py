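"""Expression-stratified metagene profiles and RPKM-based gene grouping.

Profiles cover TSS-3 kb .. TSS .. gene body .. TES .. TES+5 kb with 50-bp
flank windows (60 upstream, 100 downstream) and 100 body windows each 1%
of the gene's length.  Window counts use strand-aware shifted read
positions; on the minus strand the window layout is mirrored so that
window 0 is always the distal upstream end.  Densities are reads per base
per million (optionally peak-filtered) reads, averaged across the genes
of each expression group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GeneModel, GenomicInterval, TagLibrary

GROUP_LABELS = ("lowest", "low", "intermediate", "high", "highest")


@dataclass
class ProfileSpec:
    upstream: int = 3_000
    downstream: int = 5_000
    flank_window: int = 50
    body_windows: int = 100
    shift: int = 75
    peak_filtered: bool = True
    min_gene_length: int = 100

    @property
    def n_upstream(self) -> int:
        return self.upstream // self.flank_window

    @property
    def n_downstream(self) -> int:
        return self.downstream // self.flank_window

    @property
    def n_windows(self) -> int:
        return self.n_upstream + self.body_windows + self.n_downstream


def compute_rpkm(
    rna_lib: TagLibrary, genes: list[GeneModel], shift: int = 0,
) -> pd.Series:
    """Reads per kilobase of exon model per million mapped reads, per gene."""
    if rna_lib.total_mapped <= 0:
        raise ValueError("empty RNA library")
    idx = rna_lib.shifted_index(shift)
    out = {}
    for g in genes:
        if g.exonic_length == 0:
            raise ValueError(f"gene {g.name} has zero exonic length")
        arr = idx.get(g.chrom)
        n = 0
        if arr is not None and len(arr):
            for ex in g.exons:
                lo, hi = np.searchsorted(arr, [ex.start, ex.end])
                n += int(hi - lo)
        out[g.name] = n / ((g.exonic_length / 1e3) * (rna_lib.total_mapped / 1e6))
    return pd.Series(out, name="rpkm")


@dataclass
class ExpressionGroups:
    assignment: pd.Series   # gene -> group label
    inactive: pd.Series     # gene -> bool (RPKM < 1)

    def genes_in(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])


def expression_groups(rpkm: pd.Series, n_groups: int = 5) -> ExpressionGroups:
    """Equal-count expression groups by RPKM, plus the RPKM<1 inactive flag.

    Ties across a quantile boundary are broken deterministically by gene
    name.  With five groups the labels run lowest..highest.
    """
    if len(rpkm) < n_groups:
        raise ValueError("fewer genes than groups")
    if n_groups == 5:
        labels = GROUP_LABELS
    else:
        labels = tuple(f"g{i}" for i in range(n_groups))
    # deterministic tie-break: sort by (rpkm, gene name)
    ranked = sorted(rpkm.index, key=lambda g: (rpkm[g], g))
    n = len(ranked)
    bounds = [round(i * n / n_groups) for i in range(n_groups + 1)]
    assignment = pd.Series(index=rpkm.index, dtype=object)
    for gi in range(n_groups):
        for g in ranked[bounds[gi]:bounds[gi + 1]]:
            assignment[g] = labels[gi]
    inactive = rpkm < 1.0
    if inactive.all():
        warnings.warn("all genes inactive (RPKM < 1); expression grouping degenerate")
    return ExpressionGroups(assignment, inactive)


def _peak_filter(
    positions: np.ndarray, peaks_by_chrom: dict[str, np.ndarray], chrom: str,
) -> np.ndarray:
    """Boolean mask of positions inside the (merged, sorted) peak set."""
    edges = peaks_by_chrom.get(chrom)
    if edges is None or len(edges) == 0:
        return np.zeros(len(positions), dtype=bool)
    return np.searchsorted(edges, positions, side="right") % 2 == 1


def _merged_edges(peaks: list[GenomicInterval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged).ravel()
    return out


def _gene_window_edges(g: GeneModel, spec: ProfileSpec) -> np.ndarray:
    """Genomic window edges, ordered 5'->3' along the gene (flip for minus)."""
    if g.strand == "+":
        up = np.arange(g.tss - spec.upstream, g.tss + 1, spec.flank_window)
        body = np.linspace(g.tss, g.tes, spec.body_windows + 1)
        down = np.arange(g.tes, g.tes + spec.downstream + 1, spec.flank_window)
        return np.concatenate([up[:-1], body[:-1], down])
    up = np.arange(g.tss + spec.upstream, g.tss - 1, -spec.flank_window)
    body = np.linspace(g.tss, g.tes, spec.body_windows + 1)
    down = np.arange(g.tes, g.tes - spec.downstream - 1, -spec.flank_window)
    return np.concatenate([up[:-1], body[:-1], down])


def compute_profile(
    lib: TagLibrary,
    genes: list[GeneModel],
    spec: ProfileSpec | None = None,
    groups: ExpressionGroups | None = None,
    peaks: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Average read-density profile per expression group.

    Returns a DataFrame (rows = group labels, columns = 0..n_windows-1 of
    reads per base per million normalizing reads).  With
    ``spec.peak_filtered`` and a peak set, only reads whose shifted
    position falls inside a peak are counted and the normalizing total is
    the library's peak-filtered read count.  Genes shorter than
    ``min_gene_length`` are skipped (a warning reports how many).
    """
    spec = spec or ProfileSpec()
    idx = lib.shifted_index(spec.shift)
    filtering = spec.peak_filtered and peaks is not None
    if filtering:
        edges_by_chrom = _merged_edges(peaks)
        filtered: dict[str, np.ndarray] = {}
        norm_total = 0
        for chrom, pos in idx.items():
            mask = _peak_filter(pos, edges_by_chrom, chrom)
            filtered[chrom] = pos[mask]
            norm_total += int(mask.sum())
        positions = filtered
    else:
        positions = idx
        norm_total = lib.total_mapped
    if norm_total == 0:
        raise ValueError("no reads available for profile normalization")

    usable = [g for g in genes if g.length >= max(spec.min_gene_length, spec.body_windows)]
    skipped = len(genes) - len(usable)
    if skipped:
        warnings.warn(f"{skipped} genes shorter than the body-window minimum were excluded")
    if groups is None:
        gene_group = {g.name: "all" for g in usable}
        labels = ["all"]
    else:
        gene_group = dict(groups.assignment)
        labels = list(dict.fromkeys(groups.assignment))
    sums: dict[str, np.ndarray] = {lb: np.zeros(spec.n_windows) for lb in labels}
    counts: dict[str, int] = {lb: 0 for lb in labels}
    for g in usable:
        lb = gene_group.get(g.name)
        if lb is None:
            continue
        edges = _gene_window_edges(g, spec)
        pos = positions.get(g.chrom, np.array([]))
        if g.strand == "+":
            c = np.diff(np.searchsorted(pos, edges))
            bases = np.diff(edges)
        else:
            c = np.diff(np.searchsorted(pos, edges[::-1]))[::-1]
            bases = -np.diff(edges)
        dens = c / np.maximum(bases, 1e-9)
        sums[lb] += dens
        counts[lb] += 1
    rows = {}
    for lb in labels:
        if counts[lb] == 0:
            continue
        rows[lb] = sums[lb] / counts[lb] / (norm_total / 1e6)
    return pd.DataFrame(rows).T


def timecourse_profiles(
    libraries: list[TagLibrary],
    genes: list[GeneModel],
    spec: ProfileSpec | None = None,
    groups: ExpressionGroups | None = None,
    peaks: list[GenomicInterval] | None = None,
) -> dict[float, pd.DataFrame]:
    """Per-time-point profiles, keyed and ordered by hours."""
    if len(libraries) < 2:
        raise ValueError("need at least 2 libraries")
    libs = sorted(libraries, key=lambda lb: lb.hours)
    return {lb.hours: compute_profile(lb, genes, spec, groups, peaks) for lb in libs}


def profiles_long_table(profiles: dict[float, pd.DataFrame], spec: ProfileSpec) -> pd.DataFrame:
    """Long-format (time, group, region, window, density) table."""
    spec = spec or ProfileSpec()
    rows = []
    for hours, df in profiles.items():
        for group, series in df.iterrows():
            for w, dens in enumerate(series.values):
                if w < spec.n_upstream:
                    region = "upstream"
                elif w < spec.n_upstream + spec.body_windows:
                    region = "body"
                else:
                    region = "downstream"
                rows.append((hours, group, region, w, dens))
    return pd.DataFrame(rows, columns=["hours", "group", "region", "window", "density"])
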
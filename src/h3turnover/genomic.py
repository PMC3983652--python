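"""Genomic coordinate types, tag libraries, and the plain-text formats the pipeline reads.

All coordinates are 0-based half-open (BED-native) throughout the package.
refFlat-style gene tables are converted to this convention on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint position (floor division), used for peak annotation."""
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene with strand-oriented TSS/TES and a sorted, non-overlapping exon list.

    ``tss``/``tes`` are oriented: for a minus-strand gene the TSS is the larger
    coordinate.  ``cds_start``/``cds_end`` are unoriented genomic coordinates
    bounding the coding region; exonic sequence between the TSS and the CDS is
    the 5' UTR, between the CDS and the TES the 3' UTR.
    """

    name: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    rpkm: float | None = None
    expression: float | None = None  # latent level used by the simulator

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.name}: zero-length gene")
        if (self.strand == "+") != (self.tss < self.tes):
            raise ValueError(f"gene {self.name}: tss/tes not oriented by strand")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.name}: exon on wrong chromosome")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or unsorted")
            prev_end = ex.end
        if self.exons:
            if self.exons[0].start < self.start or self.exons[-1].end > self.end:
                raise ValueError(f"gene {self.name}: exon outside gene span")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.name)


class TagLibrary:
    """A set of mapped read positions with library metadata.

    Tags are stored as parallel numpy arrays (chromosome code, position,
    strand code 0/1 for +/-).  Position is the 5' end of the read; counting
    uses strand-aware shifted positions (+: pos+shift, -: pos-shift), the
    shift approximating half the fragment length.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        strand: np.ndarray,
        label: str = "",
        hours: float = 0.0,
        chrom_names: list[str] | None = None,
    ) -> None:
        if chrom_names is None:
            # chrom given as array of strings
            names, codes = np.unique(np.asarray(chrom, dtype=object), return_inverse=True)
            self.chrom_names = [str(c) for c in names]
            self.chrom_codes = codes.astype(np.int32)
        else:
            self.chrom_names = list(chrom_names)
            self.chrom_codes = np.asarray(chrom, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.strand_codes = np.asarray(strand, dtype=np.int8)
        if not (len(self.pos) == len(self.chrom_codes) == len(self.strand_codes)):
            raise ValueError("chrom/pos/strand arrays must have equal length")
        if hours < 0:
            raise ValueError("hours must be >= 0")
        self.label = label
        self.hours = float(hours)
        self._index_cache: dict[int, dict[str, np.ndarray]] = {}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_tags(
        cls, tags: list[tuple[str, int, str]], label: str = "", hours: float = 0.0
    ) -> "TagLibrary":
        if not tags:
            return cls(np.array([], dtype=np.int32), np.array([], dtype=np.int64),
                       np.array([], dtype=np.int8), label, hours, chrom_names=[])
        chroms = np.array([t[0] for t in tags], dtype=object)
        pos = np.array([t[1] for t in tags], dtype=np.int64)
        strand = np.array([0 if t[2] == "+" else 1 for t in tags], dtype=np.int8)
        return cls(chroms, pos, strand, label, hours)

    # -- basic properties -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def total_mapped(self) -> int:
        return len(self.pos)

    def tags(self) -> list[tuple[str, int, str]]:
        """Materialize tags as (chrom, pos, strand) tuples (small libraries only)."""
        return [
            (self.chrom_names[c], int(p), "+" if s == 0 else "-")
            for c, p, s in zip(self.chrom_codes, self.pos, self.strand_codes)
        ]

    # -- operations -----------------------------------------------------------

    def deduplicate(self) -> "TagLibrary":
        """Keep at most one tag per (chromosome, position, strand)."""
        key = (self.chrom_codes.astype(np.int64) << 34) | (self.pos << 1) | self.strand_codes
        _, idx = np.unique(key, return_index=True)
        idx.sort()
        return TagLibrary(
            self.chrom_codes[idx], self.pos[idx], self.strand_codes[idx],
            self.label, self.hours, chrom_names=self.chrom_names,
        )

    def shifted_index(self, shift: int) -> dict[str, np.ndarray]:
        """Per-chromosome sorted arrays of strand-shifted tag positions."""
        if shift < 0:
            raise ValueError("shift must be >= 0")
        if shift not in self._index_cache:
            shifted = np.where(self.strand_codes == 0, self.pos + shift, self.pos - shift)
            index: dict[str, np.ndarray] = {}
            for code, name in enumerate(self.chrom_names):
                sel = shifted[self.chrom_codes == code]
                sel.sort()
                index[name] = sel
            self._index_cache[shift] = index
        return self._index_cache[shift]


def deduplicate_tags(lib: TagLibrary) -> TagLibrary:
    return lib.deduplicate()


def count_tags(lib: TagLibrary, region: GenomicInterval, shift: int = 75) -> int:
    """Count tags whose shifted position lies in the half-open region."""
    idx = lib.shifted_index(shift)
    arr = idx.get(region.chrom)
    if arr is None or len(arr) == 0:
        return 0
    lo, hi = np.searchsorted(arr, [region.start, region.end])
    return int(hi - lo)


def count_tags_many(
    lib: TagLibrary, regions: list[GenomicInterval], shift: int = 75
) -> np.ndarray:
    """Vectorized :func:`count_tags` over a list of regions."""
    idx = lib.shifted_index(shift)
    out = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        arr = idx.get(region.chrom)
        if arr is None or len(arr) == 0:
            continue
        lo, hi = np.searchsorted(arr, [region.start, region.end])
        out[i] = hi - lo
    return out


def normalize_count(count: int, total_mapped: int) -> float:
    """Tags per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count * 1e6 / total_mapped


# -- BED ----------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (0-based half-open)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_tag_bed(path: str | Path, label: str = "", hours: float = 0.0) -> TagLibrary:
    """Read a BED6 tag file into a :class:`TagLibrary` (position = BED start)."""
    chroms: list[str] = []
    pos: list[int] = []
    strand: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            chroms.append(fields[0])
            pos.append(start)
            strand.append(1 if len(fields) > 5 and fields[5] == "-" else 0)
    if not chroms:
        return TagLibrary.from_tags([], label=label, hours=hours)
    return TagLibrary(np.array(chroms, dtype=object), np.array(pos), np.array(strand),
                      label=label, hours=hours)


def write_tag_bed(lib: TagLibrary, path: str | Path, read_length: int = 50) -> None:
    with open(path, "w") as fh:
        for code, p, s in zip(lib.chrom_codes, lib.pos, lib.strand_codes):
            strand = "+" if s == 0 else "-"
            fh.write(
                f"{lib.chrom_names[code]}\t{p}\t{p + read_length}\t{lib.label or 'tag'}\t0\t{strand}\n"
            )


# -- refFlat-style gene tables ------------------------------------------------

_REFFLAT_COLS = 11  # geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds


def read_refflat(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < _REFFLAT_COLS:
                raise ValueError(f"{path}:{lineno}: expected {_REFFLAT_COLS} columns")
            chrom, strand = f[2], f[3]
            tx_start, tx_end = int(f[4]), int(f[5])
            cds_start, cds_end = int(f[6]), int(f[7])
            ex_starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
            ex_ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            exons = [GenomicInterval(chrom, s, e) for s, e in zip(ex_starts, ex_ends)]
            tss, tes = (tx_start, tx_end) if strand == "+" else (tx_end, tx_start)
            genes.append(
                GeneModel(f[0], chrom, strand, tss, tes, exons,
                          cds_start=cds_start, cds_end=cds_end)
            )
    return genes


def write_refflat(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(ex.start) for ex in g.exons) + ","
            ends = ",".join(str(ex.end) for ex in g.exons) + ","
            cds_s = g.cds_start if g.cds_start is not None else g.start
            cds_e = g.cds_end if g.cds_end is not None else g.start
            fh.write(
                f"{g.name}\t{g.name}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}"
                f"\t{cds_s}\t{cds_e}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )
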
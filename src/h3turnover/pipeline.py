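"""End-to-end orchestration: dedup -> peak calling -> TI -> annotation -> profiles.

The pipeline can run fully in memory (:func:`run_analysis`, the form used
by the test-suite and the acceptance script) or file-driven from a TSV
library manifest and YAML config (:func:`run_pipeline`), producing TSV
result tables and a JSON run report with content digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, islands, marks, metagene, turnover
from .genomic import (GeneModel, GenomicInterval, TagLibrary, read_bed,
                      read_refflat, read_tag_bed)

log = logging.getLogger("h3turnover")

MANIFEST_COLUMNS = ("path", "role", "hours", "replicate")


@dataclass
class AnalysisParams:
    shift: int = 75
    island: islands.IslandParams = field(default_factory=islands.IslandParams)
    time_axis: str = "ordinal"
    overlap_frac: float = 0.10
    n_expression_groups: int = 5
    profile: metagene.ProfileSpec = field(default_factory=metagene.ProfileSpec)
    seed: int = 0


@dataclass
class AnalysisResult:
    peaks: list                           # Island objects from the final time point
    peak_universe: list[GenomicInterval]
    series: list[turnover.PeakTimeCourse]
    fits: list[turnover.TurnoverFit]
    bimodal: turnover.BimodalResult | None
    region_labels: list[str]
    category_summary: pd.DataFrame
    center_annotation: dict
    category_enrichment: list
    repeat_timecourse: pd.DataFrame | None
    rpkm: pd.Series | None
    groups: metagene.ExpressionGroups | None
    profiles: dict | None
    mark_matrix: marks.MarkMatrix | None


def run_analysis(
    chip_libs: list[TagLibrary],
    input_lib: TagLibrary,
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    repeat_blocks: list[tuple[GenomicInterval, str]] | None = None,
    mark_sets: dict[str, list[GenomicInterval]] | None = None,
    mark_libs: dict[str, TagLibrary] | None = None,
    rna_lib: TagLibrary | None = None,
    params: AnalysisParams | None = None,
    with_profiles: bool = True,
    replicate_id: str = "",
) -> AnalysisResult:
    """Run the analysis stages on in-memory libraries.

    Stage order: dedup -> island calling on the final time point -> per-peak
    enrichment series -> truncated-regression turnover indices -> scaling &
    bimodal classification -> genomic-category and repeat summaries ->
    expression grouping and metagene profiles -> mark matrix.
    """
    params = params or AnalysisParams()
    if not chip_libs:
        raise ValueError("no ChIP libraries")
    libs = sorted((lb.deduplicate() for lb in chip_libs), key=lambda lb: lb.hours)
    inp = input_lib.deduplicate()
    final = libs[-1]
    log.info("calling islands on the %gh library (%d tags)", final.hours, len(final))
    peaks = islands.call_peaks(final, inp, chrom_lengths, params.island, params.shift)
    universe = [p.region for p in peaks]
    log.info("%d peaks in the universe", len(universe))
    series = turnover.enrichment_series(universe, libs, inp, params.shift,
                                        replicate_id=replicate_id)
    fits = [turnover.fit_turnover(tc, params.time_axis) for tc in series]
    if len(fits) >= 2:
        turnover.scale_indices(fits, "linear")
        turnover.scale_indices(fits, "log")
    bimodal = None
    if len(fits) >= 50:
        bimodal = turnover.classify_bimodal(fits, random_state=params.seed)

    catmap = annotate.CategoryMap(genes, chrom_lengths)
    center_annotation = dict(annotate.annotate_peak_centers(universe, catmap)) if universe else {}
    cat_enrich = annotate.category_enrichment(final, inp, catmap, params.shift)
    region_labels = annotate.classify_peak_regions(
        universe, genes, catmap, mark_sets, repeat_blocks,
        overlap_frac=params.overlap_frac,
    )
    category_summary = annotate.category_turnover_summary(fits, region_labels)
    repeat_tc = None
    if repeat_blocks:
        repeat_tc = annotate.repeat_timecourse(libs, inp, repeat_blocks, params.shift)

    rpkm = groups = profiles = None
    if rna_lib is not None and genes:
        rpkm = metagene.compute_rpkm(rna_lib, genes)
        groups = metagene.expression_groups(rpkm, params.n_expression_groups)
        if with_profiles:
            profiles = metagene.timecourse_profiles(libs, genes, params.profile,
                                                    groups, universe)
    mark_matrix = None
    if mark_sets:
        mark_matrix = marks.build_mark_matrix(universe, mark_sets, mark_libs,
                                              params.overlap_frac, params.shift)
    return AnalysisResult(
        peaks=peaks, peak_universe=universe, series=series, fits=fits,
        bimodal=bimodal, region_labels=region_labels,
        category_summary=category_summary, center_annotation=center_annotation,
        category_enrichment=cat_enrich, repeat_timecourse=repeat_tc,
        rpkm=rpkm, groups=groups, profiles=profiles, mark_matrix=mark_matrix,
    )


# -- manifest -----------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def validate_manifest(manifest: pd.DataFrame, check_paths: bool = True) -> list[str]:
    """Return a list of human-readable manifest problems (empty if valid)."""
    issues: list[str] = []
    roles = manifest["role"].astype(str)
    for rep, sub in manifest.groupby("replicate"):
        n_input = (sub["role"] == "input").sum()
        if n_input != 1:
            issues.append(f"replicate {rep}: expected exactly 1 input row, found {n_input}")
        chip = sub[sub["role"] == "chip"]
        dup = chip["hours"][chip["hours"].duplicated(keep=False)]
        if len(dup):
            rows = sorted(dup.index.tolist())
            issues.append(f"replicate {rep}: duplicate chip hours {sorted(set(dup))} in rows {rows}")
    for i, row in manifest.iterrows():
        role = str(row["role"])
        if role not in ("chip", "input", "rna") and not role.startswith("mark:"):
            issues.append(f"row {i}: unknown role {role!r}")
        if role == "chip" and (pd.isna(row["hours"]) or row["hours"] < 0):
            issues.append(f"row {i}: chip row needs hours >= 0")
        if check_paths and not Path(str(row["path"])).exists():
            issues.append(f"row {i}: path does not exist: {row['path']}")
    return issues


@dataclass
class RunReport:
    params: dict
    counts: dict
    outputs: dict
    digests: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    manifest_path: str | Path,
    outdir: str | Path,
    params: AnalysisParams | None = None,
    chrom_lengths_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    repeats_path: str | Path | None = None,
) -> RunReport:
    """File-driven pipeline: load the manifest's libraries, analyse, write tables."""
    params = params or AnalysisParams()
    manifest = read_manifest(manifest_path)
    issues = validate_manifest(manifest)
    if issues:
        raise ValueError("manifest validation failed:\n" + "\n".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chip_libs, mark_libs = [], {}
    input_lib = rna_lib = None
    for _, row in manifest.iterrows():
        role = str(row["role"])
        hours = float(row["hours"]) if not pd.isna(row["hours"]) else 0.0
        lib = read_tag_bed(row["path"], label=role, hours=hours)
        if role == "chip":
            chip_libs.append(lib)
        elif role == "input":
            input_lib = lib
        elif role == "rna":
            rna_lib = lib
        elif role.startswith("mark:"):
            mark_libs[role.split(":", 1)[1]] = lib
    genes = read_refflat(genes_path) if genes_path else []
    repeat_blocks = None
    if repeats_path:
        repeat_blocks = [(iv, iv.name) for iv in read_bed(repeats_path)]
    if chrom_lengths_path:
        chrom_lengths = {}
        with open(chrom_lengths_path) as fh:
            for line in fh:
                c, L = line.split()
                chrom_lengths[c] = int(L)
    else:
        # fall back to the observed tag extent
        chrom_lengths = {}
        for lib in chip_libs + [input_lib]:
            for code, name in enumerate(lib.chrom_names):
                sel = lib.pos[lib.chrom_codes == code]
                if len(sel):
                    chrom_lengths[name] = max(chrom_lengths.get(name, 0), int(sel.max()) + 1_000)

    mark_sets = None  # file-driven mark peak sets come from mark BEDs if provided
    result = run_analysis(chip_libs, input_lib, genes, chrom_lengths,
                          repeat_blocks, mark_sets, mark_libs, rna_lib, params)

    outputs: dict[str, str] = {}
    islands.write_islands(result.peaks, outdir / "peaks.tsv")
    outputs["peaks"] = str(outdir / "peaks.tsv")
    turnover.fits_table(result.fits).assign(region=result.region_labels).to_csv(
        outdir / "turnover.tsv", sep="\t", index=False)
    outputs["turnover"] = str(outdir / "turnover.tsv")
    result.category_summary.to_csv(outdir / "category_turnover.tsv", sep="\t")
    outputs["category_turnover"] = str(outdir / "category_turnover.tsv")
    pd.DataFrame([dataclasses.asdict(c) for c in result.category_enrichment]).to_csv(
        outdir / "category_enrichment.tsv", sep="\t", index=False)
    outputs["category_enrichment"] = str(outdir / "category_enrichment.tsv")
    if result.repeat_timecourse is not None:
        result.repeat_timecourse.to_csv(outdir / "repeat_timecourse.tsv", sep="\t")
        outputs["repeat_timecourse"] = str(outdir / "repeat_timecourse.tsv")
    if result.profiles is not None:
        metagene.profiles_long_table(result.profiles, params.profile).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False)
        outputs["profiles"] = str(outdir / "profiles.tsv")

    counts = {
        "libraries": len(chip_libs),
        "peaks_called": len(result.peaks),
        "peaks_fit": len(result.fits),
        "genes": len(genes),
    }
    report = RunReport(
        params={
            "shift": params.shift, "time_axis": params.time_axis,
            "window": params.island.window, "gap": params.island.gap,
            "island_fdr": params.island.island_fdr,
            "overlap_frac": params.overlap_frac, "seed": params.seed,
        },
        counts=counts, outputs=outputs,
        digests={k: _digest(Path(v)) for k, v in outputs.items()},
        warnings=[],
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
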
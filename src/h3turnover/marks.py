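"""Histone-mark association with nucleosome turnover.

Builds a peaks x marks presence/level matrix (presence via the 10%
shorter-peak overlap rule, level as mark tag density within the peak),
then quantifies the turnover relationship three ways: quantile-binned
mean TI per mark level, combinatorial presence/absence group comparisons
(all-five active marks vs missing-one, none vs only-one, only-active vs
+H3K27me3/+H3K36me3) with two-sided Mann-Whitney rank-sum tests, and a
TI-sorted table for heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import overlap_peaks
from .genomic import GenomicInterval, TagLibrary, count_tags_many
from .turnover import TurnoverFit

ACTIVE_SET = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H2A.Z")


@dataclass
class MarkMatrix:
    peaks: list[GenomicInterval]
    presence: pd.DataFrame  # bool, rows aligned to peaks
    level: pd.DataFrame     # mark tags per million per kb within the peak


def build_mark_matrix(
    peaks: list[GenomicInterval],
    mark_peak_sets: dict[str, list[GenomicInterval]],
    mark_libs: dict[str, TagLibrary] | None = None,
    overlap_frac: float = 0.10,
    shift: int = 75,
) -> MarkMatrix:
    """Presence (overlap rule) and level (normalized density) per peak and mark."""
    mark_libs = mark_libs or {}
    presence = pd.DataFrame(False, index=range(len(peaks)), columns=list(mark_peak_sets))
    level = pd.DataFrame(np.nan, index=range(len(peaks)), columns=list(mark_peak_sets))
    for mark, mset in mark_peak_sets.items():
        if mset:
            pairs, _ = overlap_peaks(peaks, mset, overlap_frac)
            for i, _ in pairs:
                presence.loc[i, mark] = True
        lib = mark_libs.get(mark)
        if lib is not None and lib.total_mapped > 0:
            counts = count_tags_many(lib, peaks, shift)
            kb = np.array([p.length / 1e3 for p in peaks])
            level[mark] = counts * 1e6 / lib.total_mapped / kb
    return MarkMatrix(peaks, presence, level)


def bin_by_level(
    matrix: MarkMatrix, fits: list[TurnoverFit], mark: str,
    n_bins: int = 4, equal_width: bool = False,
) -> pd.DataFrame:
    """Mean scaled TI per mark-level bin (equal-count quantile bins by default).

    Ties are broken deterministically by peak order.  Returns one row per
    bin with its level boundaries, size and mean TI.
    """
    if mark not in matrix.level.columns:
        raise KeyError(f"no level data for mark {mark}")
    levels = matrix.level[mark].to_numpy()
    ti = np.array([f.ti_scaled for f in fits])
    ok = ~np.isnan(levels)
    if ok.sum() < n_bins:
        raise ValueError("fewer peaks with defined level than bins")
    levels, ti = levels[ok], ti[ok]
    if equal_width:
        edges = np.linspace(levels.min(), levels.max(), n_bins + 1)
        which = np.clip(np.digitize(levels, edges[1:-1]), 0, n_bins - 1)
    else:
        order = np.argsort(levels, kind="stable")
        which = np.empty(len(levels), dtype=int)
        bounds = [round(i * len(levels) / n_bins) for i in range(n_bins + 1)]
        for b in range(n_bins):
            which[order[bounds[b]:bounds[b + 1]]] = b
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        rows.append({
            "bin": b, "n": int(sel.sum()),
            "level_lo": float(levels[sel].min()), "level_hi": float(levels[sel].max()),
            "mean_ti": float(ti[sel].mean()),
        })
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]   # group name -> TI values
    table: pd.DataFrame             # comparisons vs the family reference
    vacuous: bool = False


def combinatorial_groups(
    matrix: MarkMatrix, fits: list[TurnoverFit],
    active_set: tuple[str, ...] = ACTIVE_SET,
) -> GroupComparison:
    """Presence-pattern groups of active marks and their TI comparisons.

    Groups: ``all_active`` (all five present), ``missing_<m>`` (exactly m
    absent), ``none_active``, ``only_<m>`` (exactly m present),
    ``only_active`` (all five, neither H3K27me3 nor H3K36me3),
    ``active_plus_H3K27me3`` / ``active_plus_H3K36me3`` / ``active_plus_both``.
    Each family is tested against its reference group (all_active,
    none_active and only_active respectively) with two-sided Mann-Whitney
    rank-sum tests; q-values are Benjamini-Hochberg within family.
    """
    pres = matrix.presence
    missing = [m for m in active_set if m not in pres.columns]
    if missing:
        raise KeyError(f"presence matrix lacks marks: {missing}")
    ti = np.array([f.ti_scaled for f in fits])
    if len(ti) != len(pres):
        raise ValueError("fits and matrix must align")
    act = pres[list(active_set)].to_numpy()
    n_act = act.sum(axis=1)
    k27 = pres["H3K27me3"].to_numpy() if "H3K27me3" in pres else np.zeros(len(ti), bool)
    k36 = pres["H3K36me3"].to_numpy() if "H3K36me3" in pres else np.zeros(len(ti), bool)

    groups: dict[str, np.ndarray] = {}
    all_active = n_act == len(active_set)
    groups["all_active"] = ti[all_active]
    for i, m in enumerate(active_set):
        sel = (~act[:, i]) & (n_act == len(active_set) - 1)
        groups[f"missing_{m}"] = ti[sel]
    groups["none_active"] = ti[n_act == 0]
    for i, m in enumerate(active_set):
        sel = act[:, i] & (n_act == 1)
        groups[f"only_{m}"] = ti[sel]
    only_active = all_active & ~k27 & ~k36
    groups["only_active"] = ti[only_active]
    groups["active_plus_H3K27me3"] = ti[all_active & k27 & ~k36]
    groups["active_plus_H3K36me3"] = ti[all_active & k36 & ~k27]
    groups["active_plus_both"] = ti[all_active & k27 & k36]

    families = {
        "missing_one": ("all_active", [f"missing_{m}" for m in active_set]),
        "only_one": ("none_active", [f"only_{m}" for m in active_set]),
        "repressive": ("only_active", ["active_plus_H3K27me3",
                                       "active_plus_H3K36me3", "active_plus_both"]),
    }
    rows = []
    for family, (ref, members) in families.items():
        ref_ti = groups[ref]
        fam_rows = []
        for name in members:
            g = groups[name]
            if len(g) == 0 or len(ref_ti) == 0:
                fam_rows.append({"family": family, "group": name, "reference": ref,
                                 "n": len(g), "n_ref": len(ref_ti),
                                 "median": np.nan, "median_ref": np.nan,
                                 "p": np.nan})
                continue
            stat, p = stats.mannwhitneyu(g, ref_ti, alternative="two-sided")
            fam_rows.append({"family": family, "group": name, "reference": ref,
                             "n": len(g), "n_ref": len(ref_ti),
                             "median": float(np.median(g)),
                             "median_ref": float(np.median(ref_ti)),
                             "p": float(p)})
        ps = [r["p"] for r in fam_rows if np.isfinite(r["p"])]
        if ps:
            _, qs, _, _ = multipletests(ps, method="fdr_bh")
            qi = iter(qs)
            for r in fam_rows:
                r["q"] = float(next(qi)) if np.isfinite(r["p"]) else np.nan
        else:
            for r in fam_rows:
                r["q"] = np.nan
        rows += fam_rows
    table = pd.DataFrame(rows)
    vacuous = bool(table["p"].isna().all())
    return GroupComparison(groups, table, vacuous)


def sorted_heatmap_table(matrix: MarkMatrix, fits: list[TurnoverFit]) -> pd.DataFrame:
    """Peaks sorted by scaled TI ascending with per-mark levels (heatmap input)."""
    if len(fits) != len(matrix.presence):
        raise ValueError("fits and matrix must align")
    df = pd.DataFrame({
        "chrom": [f.peak.chrom for f in fits],
        "start": [f.peak.start for f in fits],
        "end": [f.peak.end for f in fits],
        "ti_scaled": [f.ti_scaled for f in fits],
    })
    for mark in matrix.level.columns:
        df[mark] = matrix.level[mark].to_numpy()
    return df.sort_values(
        by=["ti_scaled", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


def fast_slow_mark_comparison(
    matrix: MarkMatrix, fits: list[TurnoverFit], labels: np.ndarray,
) -> pd.DataFrame:
    """Per-mark level medians in fast- vs slow-turnover peaks, with rank-sum P."""
    labels = np.asarray(labels)
    fast = labels == "fast"
    slow = labels == "slow"
    if fast.sum() == 0 or slow.sum() == 0:
        raise ValueError("both fast and slow groups must be non-empty")
    rows = []
    for mark in matrix.level.columns:
        lv = matrix.level[mark].to_numpy()
        a, b = lv[fast], lv[slow]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            continue
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"mark": mark, "median_fast": float(np.median(a)),
                     "median_slow": float(np.median(b)), "p": float(p)})
    return pd.DataFrame(rows)
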
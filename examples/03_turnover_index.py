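"""Fit per-peak turnover indices and check recovery of the true kinetics.

The TI is the slope of enrichment vs time-point index, with the fit end
point chosen between the enrichment maximum and 72 h by smallest slope
P-value; indices are then min-max scaled to [0, 1].
"""
from scipy import stats

from h3turnover import SimConfig, run_analysis, simulate_dataset
from h3turnover.simulate import match_peaks_to_sites

ds = simulate_dataset(SimConfig(seed=1))
res = run_analysis(ds.chip_libs, ds.input_lib, ds.genome.genes,
                   ds.genome.chromosomes, ds.genome.repeat_blocks,
                   ds.mark_sets, ds.mark_libs, ds.rna_lib, with_profiles=False)

sites = match_peaks_to_sites(res.peak_universe, ds.genome.sites)
pairs = [(s.k, f.ti_scaled) for s, f in zip(sites, res.fits) if s is not None]
ks, tis = zip(*pairs)
rho = stats.spearmanr(ks, tis).statistic
print(f"{len(res.fits)} peaks fit; {len(pairs)} matched to truth sites")
print(f"Spearman(true k, scaled TI) = {rho:.3f}")
print("\nmean scaled TI by functional region:")
print(res.category_summary[["n", "mean_ti", "median_ti"]].round(3).to_string())
# A high Spearman correlation means the linear TI ranks sites by their
# true first-order exchange rate; the region table shows the
# promoter > enhancer > gene body > telomere ordering.
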
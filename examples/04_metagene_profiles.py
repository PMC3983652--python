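"""Expression-stratified metagene profiles across the induction series.

Read density in 50-bp flank windows and 1%-of-gene body windows shows
promoter H3.3 appearing within hours while gene-body incorporation only
emerges after the 6 h point and keeps rising to 72 h.
"""
from h3turnover import ProfileSpec, SimConfig, simulate_dataset
from h3turnover.metagene import timecourse_profiles

ds = simulate_dataset(SimConfig(seed=1))
libs = [lb.deduplicate() for lb in ds.chip_libs]
active = [g for g in ds.genome.genes if (g.expression or 0) > 0]
profs = timecourse_profiles(libs, active, ProfileSpec(peak_filtered=False))

print(" hours   TSS/background   gene-body/background")
for hours, df in profs.items():
    v = df.loc["all"].to_numpy()
    bg = v[:20].mean()                # distal upstream flank
    print(f"{hours:6g}   {v[36:60].mean()/bg:14.2f}   {v[80:140].mean()/bg:18.2f}")
# TSS signal crosses 2x background by ~1-3 h; the gene body stays below
# 2x until after the 6 h library and then rises monotonically.
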
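"""Windowed diversity statistics and Z-standardised Tajima's D from a VCF.

Loads the files written by 01_simulate_study_system.py (run that first),
computes per-population theta_W, pi and Tajima's D in 10 kb windows, and
Z-standardises Tajima's D within each population so windows are comparable
across populations with different demographic histories.
"""

from pathlib import Path

from amtscan import core_io, diversity

data = Path("example_output/simulated")

panel = core_io.read_panel(data / "panel.tsv")
mask = core_io.read_bed(data / "callable_mask.bed")
# spectrum statistics use every segregating site: a minor-allele-frequency
# cut would bias the folded SFS (and hence Tajima's D)
genotypes = core_io.read_genotypes_vcf(data / "synthetic.vcf", panel,
                                       maf_min=0.0, max_missing=0.2)
contig_lengths = {c: max(e for cc, s, e in mask if cc == c) for c, _, _ in mask}
windows = core_io.make_windows(contig_lengths, mask, window_size=10_000)

track = diversity.window_diversity_scan(genotypes, panel, windows, min_sites=500)
track = diversity.z_transform(track)

one_pop = track[track["pop"] == panel.pop_ids[0]]
print(one_pop.head(8).to_string(index=False))
print(
    f"\n{panel.pop_ids[0]}: mean z_td = {one_pop['z_td'].mean():.3f} "
    f"(0 by construction), sd = {one_pop['z_td'].std(ddof=0):.3f} (1 by construction)."
    "\nWindows with z_td > 0 carry more intermediate-frequency variation than"
    "\nthis population's genomic average (balancing-selection-like); z_td < 0"
    "\nmeans an excess of rare variants (sweep-like)."
)
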
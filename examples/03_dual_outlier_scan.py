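"""The dual outlier scan: windowed Hudson F_ST and the whitened contrast.

Runs both screens on the simulated dataset (run 01 first): the top-1%
windowed F_ST between the pooled anadromous and resident ecotypes, and the
per-SNP frequency contrast whitened by the among-population covariance and
thresholded on 10,000 pseudo-observed data (POD) replicates. Windows
flagged by both screens are the high-confidence outliers.
"""

from pathlib import Path

import numpy as np

from amtscan import core_io, divergence

data = Path("example_output/simulated")
panel = core_io.read_panel(data / "panel.tsv")
mask = core_io.read_bed(data / "callable_mask.bed")
G = core_io.read_genotypes_vcf(data / "synthetic.vcf", panel)
contig_lengths = {c: max(e for cc, s, e in mask if cc == c) for c, _, _ in mask}
windows = core_io.make_windows(contig_lengths, mask)

fst = divergence.fst_window_scan(G, panel, windows, grouping="ecotype")
# the example genome has only 120 windows, so scan the top 10% instead of
# the top 1% used at full scale
outliers, fst_thr = divergence.fst_outliers(fst, quantile=0.90)
print(f"windowed F_ST: threshold {fst_thr:.3f}, {len(outliers)} outlier windows")

freqs, n_chrom = divergence.population_frequencies(G, panel)
omega = divergence.estimate_pop_cov(freqs)
model = divergence.ContrastModel(
    pop_ids=panel.pop_ids, omega=omega, epsilon=1e-3,
    c=divergence.ecotype_contrast_vector(panel),
)
stats = divergence.contrast_stat(freqs, model)
_, pbar = divergence.standardized_residuals(freqs)
thr = divergence.pod_threshold(model, pbar[np.isfinite(stats)],
                               n_chrom=np.median(n_chrom, axis=0),
                               n_pods=10_000, quantile=0.99, seed=11)
snps = G.sites[["contig", "pos"]].copy()
snps["stat"] = stats
snps["significant"] = np.isfinite(stats) & (stats >= thr)
print(f"contrast statistic: POD threshold {thr:.2f}, "
      f"{int(snps['significant'].sum())} of {len(snps)} SNPs significant (~1% expected under neutrality)")

outset = divergence.intersect_amt_outliers(outliers, snps, fst_thr, thr)
print(f"\nhigh-confidence outliers (both screens): {len(outset.amt_windows)} windows")
print(outset.amt_windows[["contig", "start", "end", "fst", "n_significant_snps"]].to_string(index=False))
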
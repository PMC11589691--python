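"""Trait-class assignment and balancing-selection screens, end to end.

Runs the whole pipeline on the simulated dataset through the RunConfig
interface (run 01 first), then shows the four-way classification of
outlier windows by pooled standardised Tajima's D and the
balancing-selection summaries.
"""

import json
from pathlib import Path

from amtscan import core_io, pipeline

data = Path("example_output/simulated")
out = Path("example_output/run")

config = pipeline.RunConfig(
    vcf=str(data / "synthetic.vcf"),
    mask=str(data / "callable_mask.bed"),
    panel=str(data / "panel.tsv"),
    out_dir=str(out),
    fst_quantile=0.90,  # the example genome is small; full scale uses 0.99
    n_pods=5_000,
    n_perm=5_000,
    seed=11,
)
pipeline.run_all(config)
report = pipeline.summarize(out)

print("trait classes of the outlier windows (anadromous pool first):")
print(json.dumps(report["class_counts"], indent=2))
print(
    "\nLA_LR  low Tajima's D in both pools      -> opposing directional selection"
    "\nLA_MHR low in anadromous only            -> selection in migrants, relaxed in residents"
    "\nMHA_LR low in residents only             -> selection in residents"
    "\nMHA_MHR low in neither                   -> candidate balancing / relaxed selection"
)
shift = report["balancing"]["ztd_mean_shift_anadromous"]
print(
    f"\noutlier vs background pooled Tajima's D Z-score shift in the anadromous pool: "
    f"{shift['difference']:+.3f} (one-sided permutation p = {shift['p']:.4f})"
    "\nA positive shift (balancing-like) means outlier windows hold more"
    "\nintermediate-frequency variation than the background genome; a negative"
    "\nshift means the outlier set is sweep-dominated - expected here, since"
    "\nthree of the four planted regimes are directional."
)
corr = report["balancing"]["ztd_pool_correlation"]
print(
    f"\npooled Tajima's D correlation between ecotypes: outliers r = {corr['r_outlier']:+.3f}, "
    f"background r = {corr['r_background']:+.3f}"
    "\n(decorrelation at outliers indicates ecotype-specific selection pressures)"
)
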
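"""Simulate a small five-river anadromous/resident study system.

Builds a reduced synthetic dataset (2 chromosomes x 60 windows of 10 kb)
with three windows planted per selection regime, writes VCF + mask + panel
+ truth table, and prints per-population diversity so the ecotype contrast
is visible: resident (above-falls) populations show reduced Watterson's
theta and elevated Tajima's D relative to their anadromous neighbours.
"""

from pathlib import Path

from amtscan import core_io, diversity
from amtscan import synthetic_data as sd

out_dir = Path("example_output/simulated")

config = sd.DemographyConfig(n_chromosomes=2, windows_per_chromosome=60, seed=7)
plan = sd.default_selection_plan(config, per_regime=3)
dataset = sd.simulate_dataset(config, plan)
paths = sd.emit_files(dataset, out_dir)
print("wrote:", ", ".join(paths.values()))

windows = core_io.make_windows(config.contig_lengths, dataset.mask)
track = diversity.window_diversity_scan(dataset.genotypes, dataset.panel, windows)
summary = track[~track["excluded"]].groupby("pop")[["theta_w", "pi", "tajima_d"]].mean()
print("\nper-population genome means (theta_w and pi are per site):")
print(summary.round(5).to_string())
print(
    "\nEach river's resident (R) population should show lower theta_w and"
    "\nhigher Tajima's D than its anadromous (A) counterpart - the signature"
    "\nof the above-falls founder bottleneck."
)
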
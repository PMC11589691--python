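"""Shared fixtures: a small simulated study system and its pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amtscan import core_io, pipeline
from amtscan import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.DemographyConfig:
    return sd.DemographyConfig(n_chromosomes=2, windows_per_chromosome=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sd.SimulatedDataset:
    """120-window, five-river dataset with 3 planted windows per regime."""
    plan = sd.default_selection_plan(small_config, per_regime=3)
    return sd.simulate_dataset(small_config, plan)


@pytest.fixture(scope="session")
def small_files(small_dataset, tmp_path_factory) -> dict[str, str]:
    out = tmp_path_factory.mktemp("small_files")
    return sd.emit_files(small_dataset, out)


@pytest.fixture(scope="session")
def small_run(small_files, tmp_path_factory):
    """Full pipeline on the small dataset (wide scan quantile for the tiny grid)."""
    out = tmp_path_factory.mktemp("small_run")
    config = pipeline.RunConfig(
        vcf=small_files["vcf"],
        mask=small_files["mask"],
        panel=small_files["panel"],
        out_dir=str(out),
        fst_quantile=0.9,
        n_pods=2_000,
        n_perm=500,
        seed=11,
    )
    results = pipeline.run_all(config)
    return config, results


def make_panel(n_rivers: int = 1, per_pop: int = 2, rivers=None) -> core_io.PopulationPanel:
    """Minimal valid panel for hand-built genotype fixtures."""
    rivers = rivers or [f"RV{i}" for i in range(n_rivers)]
    rows = [
        (f"{river}_{eco}_{i}", river, eco, "unknown")
        for river in rivers
        for eco in ("A", "R")
        for i in range(per_pop)
    ]
    return core_io.PopulationPanel(
        pd.DataFrame(rows, columns=["sample", "river", "ecotype", "sex"])
    )


def make_genotypes(calls: np.ndarray, positions=None, contig: str = "chr1",
                   sample_ids=None) -> core_io.GenotypeMatrix:
    """Wrap a dosage array (samples x sites) as a GenotypeMatrix fixture."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    positions = list(range(100, 100 + 10 * n_sites, 10)) if positions is None else positions
    sites = pd.DataFrame(
        {
            "contig": [contig] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    return core_io.GenotypeMatrix(sample_ids=sample_ids, sites=sites, calls=calls)
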
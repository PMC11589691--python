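"""End-to-end orchestration: ingest -> diversity -> scan -> classify -> balancing.

A single :class:`RunConfig` drives the whole analysis; every stage writes
its outputs as TSV/BED/JSON into the run directory and a machine-readable
manifest records thresholds, seeds and output checksums so that any
reported number can be traced back to stage files. Runs are bit-identical
under a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balancing as bal
from . import classification as cls
from . import core_io, divergence, diversity

logger = logging.getLogger("amtscan")

STAGES = ("ingest", "diversity", "scan", "classify", "balancing")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    mask: str
    panel: str
    out_dir: str
    gff: str | None = None
    window_size: int = 10_000
    min_sites: int = 500
    maf_min: float = 0.05
    max_missing: float = 0.2
    fst_quantile: float = 0.99
    n_pods: int = 10_000
    pod_quantile: float = 0.99
    tertile_mode: str = "amt"  # or "genome"
    gene_flank: int = 10_000
    n_perm: int = 10_000
    beta_width: float = 0.15
    beta_bounds: tuple[float, float] = (0.1, 0.9)
    ridge_epsilon: float = 1e-3
    seed: int = 1

    def __post_init__(self) -> None:
        for q in (self.fst_quantile, self.pod_quantile):
            if not 0.5 < q < 1.0:
                raise core_io.ValidationError("quantiles must lie in (0.5, 1)")
        if self.tertile_mode not in ("amt", "genome"):
            raise core_io.ValidationError("tertile_mode must be 'amt' or 'genome'")
        self.beta_bounds = tuple(self.beta_bounds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_bounds"] = list(self.beta_bounds)
        return d

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed; < 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def contig_lengths_from_vcf(path) -> dict[str, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    vcf.close()
    if not lengths:
        raise core_io.FormatError(f"{path}: VCF header lists no contigs")
    return lengths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full analysis; returns the results directory.

    Any stage failure aborts with the stage name and leaves a partial
    manifest naming the completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "thresholds": {},
        "outputs": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.time()
            try:
                _STAGE_FUNCS[stage](config, state, out, manifest)
            except Exception as e:  # noqa: BLE001 - rethrown with stage context
                raise StageError(stage, e) from e
            # timings go to the log only, keeping the manifest byte-reproducible
            manifest["stages"][stage] = {"completed": True}
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    finally:
        for p in sorted(out.glob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_ingest(config: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    panel = core_io.read_panel(config.panel)
    mask = core_io.read_bed(config.mask)
    contig_lengths = contig_lengths_from_vcf(config.vcf)
    # frequency-spectrum statistics use every segregating site (a MAF cut
    # would bias the spectrum); the contrast statistic gets a stricter SNP set
    G = core_io.read_genotypes_vcf(
        config.vcf, panel, maf_min=0.0, max_missing=config.max_missing
    )
    panel.validate_against(G)
    G_snp = core_io.filter_by_maf(G, config.maf_min) if config.maf_min > 0 else G
    windows = core_io.make_windows(contig_lengths, mask, config.window_size)
    wf = core_io.windows_frame(windows)
    state.update(panel=panel, G=G, G_snp=G_snp, windows=wf, contig_lengths=contig_lengths)
    core_io.write_track(wf, out / "windows.tsv")
    manifest["thresholds"].update(
        n_sites=G.n_sites, n_snp_sites=G_snp.n_sites, n_samples=G.n_samples, n_windows=len(wf)
    )
    if config.gff:
        state["genes"] = core_io.read_gff(config.gff)


def _stage_diversity(config: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    div = diversity.window_diversity_scan(
        state["G"], state["panel"], state["windows"], min_sites=config.min_sites
    )
    div = diversity.z_transform(div)
    state["div"] = div
    core_io.write_track(div, out / "diversity.tsv")


def _stage_scan(config: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    G, panel, wf = state["G"], state["panel"], state["windows"]
    fst = divergence.fst_window_scan(G, panel, wf, grouping="ecotype", min_sites=config.min_sites)
    outliers, fst_thr = divergence.fst_outliers(fst, config.fst_quantile)
    fst_river = divergence.fst_window_scan(G, panel, wf, grouping="river", min_sites=config.min_sites)
    core_io.write_track(fst, out / "fst_windows.tsv")
    core_io.write_track(fst_river, out / "fst_windows_river.tsv")

    G_snp = state["G_snp"]
    freqs, n_chrom = divergence.population_frequencies(G_snp, panel)
    omega = divergence.estimate_pop_cov(freqs, epsilon=config.ridge_epsilon)
    model = divergence.ContrastModel(
        pop_ids=panel.pop_ids,
        omega=omega,
        epsilon=config.ridge_epsilon,
        c=divergence.ecotype_contrast_vector(panel),
    )
    stats = divergence.contrast_stat(freqs, model)
    _, pbar = divergence.standardized_residuals(freqs)
    typical_n = np.median(n_chrom, axis=0)
    thr_c = divergence.pod_threshold(
        model,
        pbar_pool=pbar[np.isfinite(stats)],
        n_chrom=typical_n,
        n_pods=config.n_pods,
        quantile=config.pod_quantile,
        seed=config.stage_seed("pods"),
    )
    snps = G_snp.sites[["contig", "pos"]].copy()
    snps["stat"] = stats
    snps["significant"] = np.isfinite(stats) & (stats >= thr_c)
    outset = divergence.intersect_amt_outliers(outliers, snps, fst_thr, thr_c)
    state["outset"] = outset
    core_io.write_track(snps, out / "contrast_snps.tsv")
    core_io.write_track(outset.amt_windows, out / "amt_windows.tsv")
    core_io.write_bed(outset.amt_windows[["contig", "start", "end"]], out / "amt_windows.bed")
    manifest["thresholds"].update(
        fst_threshold=fst_thr,
        contrast_threshold=thr_c,
        n_fst_outlier_windows=len(outliers),
        n_significant_snps=int(snps["significant"].sum()),
        n_amt_windows=len(outset.amt_windows),
        pod_seed=config.stage_seed("pods"),
    )


def _amt_mask(pooled: pd.DataFrame, amt_windows: pd.DataFrame) -> np.ndarray:
    keys = set(zip(amt_windows["contig"], amt_windows["start"]))
    return np.array([(c, s) in keys for c, s in zip(pooled["contig"], pooled["start"])])


def _stage_classify(config: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    panel = state["panel"]
    pooled = cls.pool_window_scores(state["div"], panel)
    amt = state["outset"].amt_windows
    mask = _amt_mask(pooled, amt)
    state["pooled"] = pooled
    state["amt_mask"] = mask
    pooled_amt = pooled[mask & np.isfinite(pooled["mean_z_A"]) & np.isfinite(pooled["mean_z_R"])]
    reference = pooled if config.tertile_mode == "genome" else None
    classes = cls.tertile_trait_classes(pooled_amt, reference=reference)
    result = pooled_amt.copy()
    result["trait_class"] = classes
    if "genes" in state:
        per_window, union = cls.assign_genes_to_windows(
            result, state["genes"], flank=config.gene_flank
        )
        result["genes"] = [";".join(per_window[i]) for i in result.index]
        manifest["thresholds"]["n_amt_genes"] = len(union)
        state["amt_gene_union"] = union
    state["classes"] = result
    core_io.write_track(result, out / "amt_classes.tsv")
    manifest["thresholds"]["class_counts"] = {
        c: int((result["trait_class"] == c).sum()) for c in cls.TRAIT_CLASSES
    }


def _stage_balancing(config: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    G, panel, wf = state["G"], state["panel"], state["windows"]
    pooled, mask = state["pooled"], state["amt_mask"]
    summary: dict = {}
    for pool, col in (("anadromous", "mean_z_A"), ("resident", "mean_z_R")):
        obs, p = bal.permutation_mean_shift(
            pooled.loc[mask, col],
            pooled.loc[~mask, col],
            n_perm=config.n_perm,
            seed=config.stage_seed(f"perm_{pool}"),
        )
        summary[f"ztd_mean_shift_{pool}"] = {"difference": obs, "p": p}
        enr = bal.percentile_enrichment_chisq(
            pooled.loc[mask, col].dropna(), pooled[col].dropna(), q=0.99
        )
        summary[f"ztd_top1_enrichment_{pool}"] = dataclasses.asdict(enr)
    summary["ztd_pool_correlation"] = bal.pool_correlation(pooled, mask)

    beta = bal.beta_scan(G, panel, wf, d=config.beta_width, freq_bounds=config.beta_bounds)
    core_io.write_track(beta, out / "beta_windows.tsv")
    pooled_beta = cls.pool_window_scores(beta, panel, value_col="z_beta")
    mask_beta = _amt_mask(pooled_beta, state["outset"].amt_windows)
    for pool, col in (("anadromous", "mean_z_A"), ("resident", "mean_z_R")):
        enr = bal.percentile_enrichment_chisq(
            pooled_beta.loc[mask_beta, col].dropna(), pooled_beta[col].dropna(), q=0.99
        )
        summary[f"beta_top1_enrichment_{pool}"] = dataclasses.asdict(enr)

    div = state["div"]
    eco = np.array([panel.ecotype_of(p) for p in div["pop"]])
    usable = ~div["excluded"]
    summary["theta_rank_test"] = bal.pool_rank_test(
        div.loc[usable & (eco == "A"), "theta_w"], div.loc[usable & (eco == "R"), "theta_w"]
    )
    td_fin = usable & np.isfinite(div["tajima_d"])
    summary["tajima_rank_test"] = bal.pool_rank_test(
        div.loc[td_fin & (eco == "A"), "tajima_d"], div.loc[td_fin & (eco == "R"), "tajima_d"]
    )
    state["balancing_summary"] = summary
    state["pooled_beta"] = pooled_beta
    with open(out / "balancing_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


_STAGE_FUNCS = {
    "ingest": _stage_ingest,
    "diversity": _stage_diversity,
    "scan": _stage_scan,
    "classify": _stage_classify,
    "balancing": _stage_balancing,
}


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


def summarize(results_dir) -> dict:
    """Aggregate stage outputs into a run-level report.

    Reads only stage files (diversity.tsv, amt_windows.tsv, amt_classes.tsv,
    balancing_summary.json, manifest.json), so every number is reproducible
    from them. Writes summary_populations.tsv and summary.json.
    """
    out = Path(results_dir)
    needed = ["diversity.tsv", "amt_windows.tsv", "amt_classes.tsv", "manifest.json"]
    for name in needed:
        if not (out / name).exists():
            raise core_io.ValidationError(f"missing stage output {name!r}; run the pipeline first")
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    div = core_io.read_track(out / "diversity.tsv")
    usable = ~div["excluded"]
    pop_summary = (
        div[usable]
        .groupby("pop", sort=False)
        .agg(
            n_windows=("S", "size"),
            pi=("pi", "mean"),
            theta_w=("theta_w", "mean"),
            tajima_d=("tajima_d", "mean"),
        )
        .reset_index()
    )
    core_io.write_track(pop_summary, out / "summary_populations.tsv")

    amt = core_io.read_track(out / "amt_windows.tsv")
    classes = core_io.read_track(out / "amt_classes.tsv")
    class_counts = classes["trait_class"].value_counts().to_dict()

    # outlier count vs chromosome length
    lengths = {}
    for contig, grp in div.groupby("contig"):
        lengths[contig] = int(grp["end"].max())
    per_chrom = amt.groupby("contig").size()
    counts = np.array([per_chrom.get(c, 0) for c in lengths], dtype=float)
    lens = np.array(list(lengths.values()), dtype=float)
    if len(lengths) >= 3 and counts.std() > 0 and lens.std() > 0:
        from scipy.stats import pearsonr

        r = pearsonr(counts, lens)
        chrom_corr = {"r": float(r.statistic), "p": float(r.pvalue)}
    else:
        chrom_corr = {"r": None, "p": None, "note": "not applicable (<3 chromosomes or no variation)"}

    report = {
        "populations": pop_summary.to_dict(orient="records"),
        "n_amt_windows": int(len(amt)),
        "class_counts": class_counts,
        "outliers_vs_chromosome_length": chrom_corr,
        "thresholds": manifest.get("thresholds", {}),
    }
    bpath = out / "balancing_summary.json"
    if bpath.exists():
        with open(bpath) as fh:
            report["balancing"] = json.load(fh)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
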
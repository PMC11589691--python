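"""Windowed differentiation scans and the whitened allele-frequency contrast.

Two complementary screens are combined:

* Hudson's F_ST (Bhatia et al. 2013 form) computed from called-genotype
  allele frequencies and aggregated per window as a ratio of sums
  (sum of per-site numerators over sum of per-site denominators), with the
  top-quantile windows flagged as outliers. Negative window values are kept
  as computed; ties at the threshold are all included.

* A per-SNP contrast statistic between the anadromous and resident
  population groups: per-SNP standardised frequency residuals
  z_j = (p_j - pbar) / sqrt(pbar (1 - pbar)) are whitened by the
  among-population covariance Omega (moment estimate with a small ridge),
  and the squared group contrast (c'z)^2 / (c' Omega c) is referred to a
  significance threshold calibrated on pseudo-observed data (PODs):
  neutral SNPs simulated from the fitted model, with the top-quantile POD
  statistic as the cutoff.

AMT outlier windows are F_ST outlier windows containing at least one
contrast-significant SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    GenotypeMatrix,
    PopulationPanel,
    ValidationError,
    assign_sites_to_windows,
    windows_frame,
)

__all__ = [
    "hudson_fst_site",
    "fst_window_scan",
    "fst_outliers",
    "population_frequencies",
    "ContrastModel",
    "estimate_pop_cov",
    "contrast_stat",
    "pod_threshold",
    "intersect_amt_outliers",
    "OutlierSet",
]


def hudson_fst_site(p1, n1, p2, n2):
    """Per-site Hudson F_ST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    with n1, n2 the non-missing chromosome counts. Vectorised.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValidationError("hudson_fst_site requires >= 2 chromosomes per group")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _group_freqs(G: GenotypeMatrix, sample_ids):
    rows = G.sample_indices(sample_ids)
    counts, n_chrom = G.allele_stats(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_chrom
    return p, n_chrom


def fst_window_scan(
    G: GenotypeMatrix,
    panel: PopulationPanel,
    windows,
    grouping: str = "ecotype",
    min_sites: int = 500,
) -> pd.DataFrame:
    """Windowed Hudson F_ST as ratio of sums, per comparison.

    ``grouping='ecotype'`` pools all anadromous vs all resident samples
    (comparison id ``global``); ``grouping='river'`` compares the A and R
    populations within each river. Windows with fewer than ``min_sites``
    callable bases, or with no usable site, are flagged excluded.
    """
    panel.validate_against(G)
    if grouping == "ecotype":
        comparisons = [("global", panel.samples_of_ecotype("A"), panel.samples_of_ecotype("R"))]
    elif grouping == "river":
        comparisons = [
            (river, panel.samples_of(river, "A"), panel.samples_of(river, "R"))
            for river in panel.rivers
        ]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")

    wf = windows if isinstance(windows, pd.DataFrame) else windows_frame(windows)
    widx = assign_sites_to_windows(G.sites, wf)
    n_windows = len(wf)
    out = []
    for comp, samples1, samples2 in comparisons:
        p1, n1 = _group_freqs(G, samples1)
        p2, n2 = _group_freqs(G, samples2)
        usable = (n1 >= 2) & (n2 >= 2) & (widx >= 0)
        # skip sites monomorphic in both groups (0/0 contribution)
        with np.errstate(invalid="ignore"):
            num, den = hudson_fst_site(
                np.where(usable, p1, 0.5), np.maximum(n1, 2),
                np.where(usable, p2, 0.5), np.maximum(n2, 2),
            )
        informative = usable & (den > 0)
        num_sum = np.zeros(n_windows)
        den_sum = np.zeros(n_windows)
        n_used = np.zeros(n_windows, dtype=np.int64)
        np.add.at(num_sum, widx[informative], num[informative])
        np.add.at(den_sum, widx[informative], den[informative])
        np.add.at(n_used, widx[informative], 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den_sum > 0, num_sum / den_sum, np.nan)
        excluded = (wf["callable_sites"].to_numpy() < min_sites) | (n_used == 0)
        df = wf[["contig", "start", "end"]].copy()
        df["comparison"] = comp
        df["num_sum"] = num_sum
        df["den_sum"] = den_sum
        df["n_sites"] = n_used
        df["fst"] = fst
        df["excluded"] = excluded
        out.append(df)
    return pd.concat(out, ignore_index=True)


def fst_outliers(records: pd.DataFrame, quantile: float = 0.99):
    """Top-quantile F_ST windows (inclusive at the threshold; ties all in).

    Returns ``(outliers, threshold)`` where ``outliers`` is the subset of
    non-excluded records with ``fst >= threshold``.
    """
    usable = records[~records["excluded"] & np.isfinite(records["fst"])]
    if len(usable) < 100:
        raise ValidationError("need >= 100 windows for a meaningful top-quantile scan")
    threshold = float(np.quantile(usable["fst"].to_numpy(), quantile))
    outliers = usable[usable["fst"] >= threshold].copy()
    return outliers, threshold


# ---------------------------------------------------------------------------
# contrast statistic
# ---------------------------------------------------------------------------


def population_frequencies(G: GenotypeMatrix, panel: PopulationPanel):
    """Per-population minor-allele frequencies and chromosome counts.

    Returns ``(freqs, n_chrom)`` of shape (n_sites, n_pops) in
    ``panel.pop_ids`` order; frequency is NaN where a population has no
    non-missing call.
    """
    cols_p, cols_n = [], []
    for pop in panel.pop_ids:
        p, n = _group_freqs(G, panel.samples_of_pop(pop))
        cols_p.append(p)
        cols_n.append(n)
    return np.stack(cols_p, axis=1), np.stack(cols_n, axis=1)


@dataclass
class ContrastModel:
    """Fitted among-population model for the frequency contrast statistic."""

    pop_ids: list[str]
    omega: np.ndarray
    epsilon: float
    c: np.ndarray
    pod_threshold: float | None = None
    n_pods: int = 0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not np.allclose(self.omega, self.omega.T):
            raise ValidationError("omega must be symmetric")
        if abs(self.c.sum()) > 1e-9:
            raise ValidationError("contrast vector must sum to zero")
        np.linalg.cholesky(self.omega)  # positive definiteness check

    @property
    def c_omega_c(self) -> float:
        return float(self.c @ self.omega @ self.c)


def ecotype_contrast_vector(panel: PopulationPanel) -> np.ndarray:
    """+1/k_A on anadromous populations, -1/k_R on resident ones."""
    ecos = np.array([panel.ecotype_of(p) for p in panel.pop_ids])
    c = np.where(ecos == "A", 1.0 / (ecos == "A").sum(), -1.0 / (ecos == "R").sum())
    return c


def standardized_residuals(freqs: np.ndarray):
    """Per-SNP z_j = (p_j - pbar)/sqrt(pbar(1-pbar)); NaN rows where pbar in {0,1}."""
    freqs = np.asarray(freqs, dtype=float)
    pbar = np.nanmean(freqs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (freqs - pbar[:, None]) / np.sqrt(pbar * (1 - pbar))[:, None]
    bad = (pbar <= 0) | (pbar >= 1)
    z[bad] = np.nan
    return z, pbar


def estimate_pop_cov(freqs: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Moment estimate of the among-population covariance Omega.

    ``freqs``: (n_snps, n_pops) per-population frequencies. SNPs that are
    monomorphic across all populations are skipped. The covariance of the
    standardised residuals across SNPs is regularised with a ridge
    ``epsilon * I`` to guarantee positive definiteness.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_snps, n_pops = freqs.shape
    if n_snps < 10 * n_pops:
        raise ValidationError("need >= 10x more SNPs than populations to estimate omega")
    z, _ = standardized_residuals(freqs)
    keep = np.isfinite(z).all(axis=1)
    z = z[keep]
    if len(z) == 0:
        raise ValidationError("all SNPs monomorphic across populations")
    omega = (z.T @ z) / len(z) + epsilon * np.eye(n_pops)
    return omega


def contrast_stat(freqs: np.ndarray, model: ContrastModel) -> np.ndarray:
    """(c'z)^2 / (c' Omega c) per SNP; NaN where pbar is 0 or 1.

    Approximately chi-square(1) under neutrality when the model holds.
    Accepts a single SNP vector or an (n_snps, n_pops) array.
    """
    arr = np.asarray(freqs, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != len(model.pop_ids):
        raise ValidationError("frequency vector length does not match model populations")
    z, _ = standardized_residuals(arr)
    stats = (z @ model.c) ** 2 / model.c_omega_c
    return float(stats[0]) if single else stats


def pod_threshold(
    model: ContrastModel,
    pbar_pool: np.ndarray,
    n_chrom: np.ndarray,
    n_pods: int = 10_000,
    quantile: float = 0.99,
    seed: int | None = None,
) -> float:
    """Calibrate the contrast significance threshold on pseudo-observed data.

    Each POD SNP draws an across-population mean frequency from the
    empirical pool, draws residuals from N(0, Omega), reconstructs
    per-population frequencies clipped to the observable range
    [1/(2 n_j), 1 - 1/(2 n_j)], and is scored with the same contrast
    statistic as the real data. The threshold is the requested quantile of
    the POD statistics; stored on the model. Deterministic given ``seed``.
    """
    if n_pods < 100:
        raise ValidationError("n_pods must be >= 100")
    rng = np.random.default_rng(seed)
    pbar_pool = np.asarray(pbar_pool, dtype=float)
    pbar_pool = pbar_pool[(pbar_pool > 0) & (pbar_pool < 1)]
    n_chrom = np.asarray(n_chrom, dtype=float)
    pbar = rng.choice(pbar_pool, size=n_pods, replace=True)
    L = np.linalg.cholesky(model.omega)
    z = rng.standard_normal((n_pods, len(model.pop_ids))) @ L.T
    p = pbar[:, None] + z * np.sqrt(pbar * (1 - pbar))[:, None]
    lo = 1.0 / (2.0 * n_chrom)
    p = np.clip(p, lo[None, :], 1.0 - lo[None, :])
    stats = contrast_stat(p, model)
    stats = stats[np.isfinite(stats)]
    threshold = float(np.quantile(stats, quantile))
    model.pod_threshold = threshold
    model.n_pods = n_pods
    return threshold


# ---------------------------------------------------------------------------
# outlier intersection
# ---------------------------------------------------------------------------


@dataclass
class OutlierSet:
    """F_ST outlier windows, contrast-significant SNPs, and their intersection."""

    fst_windows: pd.DataFrame
    snps: pd.DataFrame  # contig, pos, stat, significant
    amt_windows: pd.DataFrame  # fst outlier windows with >=1 significant SNP
    fst_threshold: float
    contrast_threshold: float


def intersect_amt_outliers(
    fst_outlier_windows: pd.DataFrame,
    snps: pd.DataFrame,
    fst_threshold: float = float("nan"),
    contrast_threshold: float = float("nan"),
) -> OutlierSet:
    """AMT windows: F_ST outlier windows holding >= 1 significant SNP.

    ``snps`` needs columns contig, pos (0-based), stat, significant.
    Window assignment is half-open: a SNP at ``pos == end`` falls in the
    next window.
    """
    sig = snps[snps["significant"]]
    wf = fst_outlier_windows.reset_index(drop=True)
    counts = np.zeros(len(wf), dtype=np.int64)
    if len(sig) and len(wf):
        idx = assign_sites_to_windows(
            sig.rename(columns={"pos": "pos"})[["contig", "pos"]], wf[["contig", "start", "end"]].assign(callable_sites=0)
        )
        ok = idx >= 0
        np.add.at(counts, idx[ok], 1)
    amt = wf.copy()
    amt["n_significant_snps"] = counts
    amt = amt[amt["n_significant_snps"] >= 1].reset_index(drop=True)
    return OutlierSet(
        fst_windows=wf,
        snps=snps,
        amt_windows=amt,
        fst_threshold=fst_threshold,
        contrast_threshold=contrast_threshold,
    )
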
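"""Balancing-selection screens on outlier versus background windows.

Four complementary screens:

* a permutation test for a mean shift in pooled Z-standardised Tajima's D
  between outlier windows and the genomic background (one-sided, greater);
* a one-cell goodness-of-fit chi-square for enrichment of outlier windows
  in the top percentile of a pooled score track, (O - E)^2 / E with
  E = (1 - q) * n_outliers and one degree of freedom;
* a beta-like window score of folded-allele-frequency similarity: for each
  core SNP the observed excess of window companions at similar folded
  frequency over the genome-wide expectation, maximised over cores. This
  is a concrete frequency-similarity excess statistic with the same
  construction intent as long-term balancing-selection scans (it rises
  when a window accumulates variants at matching intermediate
  frequencies); it is labelled *beta-like* throughout;
* pool-level Pearson correlations and Wilcoxon rank-sum comparisons of
  window tracks between the anadromous and resident pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    GenotypeMatrix,
    PopulationPanel,
    ValidationError,
    assign_sites_to_windows,
    windows_frame,
)
from .diversity import z_transform

__all__ = [
    "permutation_mean_shift",
    "EnrichmentResult",
    "percentile_enrichment_chisq",
    "enrichment_chisq_from_counts",
    "beta_like_score",
    "beta_scan",
    "pool_correlation",
    "pool_rank_test",
]


def permutation_mean_shift(
    z_outliers,
    z_background,
    n_perm: int = 10_000,
    seed: int | None = None,
):
    """One-sided permutation test for mean(outliers) - mean(background) > 0.

    The null shuffles outlier/background labels over the combined window
    set, keeping set sizes; p = (1 + #{diff* >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    x = np.asarray(z_outliers, dtype=float)
    y = np.asarray(z_background, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both window sets must be non-empty")
    observed = float(x.mean() - y.mean())
    combined = np.concatenate([x, y])
    n, k = len(combined), len(x)
    total = combined.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        u = rng.random((b, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        sum_out = combined[idx].sum(axis=1)
        diff = sum_out / k - (total - sum_out) / (n - k)
        hits += int((diff >= observed - 1e-12).sum())
        done += b
    p = (1 + hits) / (n_perm + 1)
    return observed, p


@dataclass
class EnrichmentResult:
    observed: int
    n_outliers: int
    expected: float
    chi_square: float
    df: int
    p_value: float


def enrichment_chisq_from_counts(observed: int, n_outliers: int, q: float = 0.99) -> EnrichmentResult:
    """(O - E)^2 / E with E = (1 - q) * n_outliers, df = 1."""
    expected = (1.0 - q) * n_outliers
    if expected <= 0:
        raise ValidationError("expected count must be positive")
    chi = (observed - expected) ** 2 / expected
    p = float(sps.chi2.sf(chi, df=1))
    return EnrichmentResult(observed, n_outliers, expected, float(chi), 1, p)


def percentile_enrichment_chisq(
    outlier_scores,
    track_scores,
    q: float = 0.99,
) -> EnrichmentResult:
    """Enrichment of outlier windows in the top (1-q) tail of a score track.

    ``track_scores`` is the pooled per-window score over the whole genome
    (outliers included); O counts outlier windows at or above the track's
    q-quantile.
    """
    outlier_scores = np.asarray(outlier_scores, dtype=float)
    track = np.asarray(track_scores, dtype=float)
    track = track[np.isfinite(track)]
    if len(outlier_scores) < 1:
        raise ValidationError("need at least one outlier window")
    if len(track) < 100:
        raise ValidationError("score track needs >= 100 windows")
    cut = np.quantile(track, q)
    observed = int(np.sum(outlier_scores >= cut))
    return enrichment_chisq_from_counts(observed, len(outlier_scores), q)


# ---------------------------------------------------------------------------
# beta-like folded-frequency similarity score
# ---------------------------------------------------------------------------

_PHI_CLASSES = np.round(np.arange(0.10, 0.501, 0.05), 2)  # 0.10 .. 0.50


def folded_class_proportions(phis: np.ndarray) -> np.ndarray:
    """Genome-wide proportions of folded frequencies over the phi classes."""
    phis = np.asarray(phis, dtype=float)
    if len(phis) == 0:
        return np.zeros_like(_PHI_CLASSES)
    idx = np.argmin(np.abs(phis[:, None] - _PHI_CLASSES[None, :]), axis=1)
    counts = np.bincount(idx, minlength=len(_PHI_CLASSES)).astype(float)
    return counts / counts.sum()


def beta_like_score(
    phis,
    class_proportions,
    d: float = 0.15,
    class_centers: np.ndarray | None = None,
) -> float:
    """Window beta-like score from folded frequencies of its usable SNPs.

    For core SNP c: s_c = sum_{i != c} max(0, 1 - |phi_i - phi_c| / d) and
    the genome-wide expectation shat_c = (S - 1) * sum_k q_k *
    max(0, 1 - |phi_k - phi_c| / d) over folded-frequency classes q.
    The window score is max_c (s_c - shat_c); NaN with < 2 usable SNPs.
    """
    phis = np.asarray(phis, dtype=float)
    if len(phis) < 2:
        return float("nan")
    centers = _PHI_CLASSES if class_centers is None else np.asarray(class_centers, dtype=float)
    q = np.asarray(class_proportions, dtype=float)
    dmat = np.abs(phis[:, None] - phis[None, :])
    w = np.clip(1.0 - dmat / d, 0.0, None)
    np.fill_diagonal(w, 0.0)
    s = w.sum(axis=1)
    wq = np.clip(1.0 - np.abs(phis[:, None] - centers[None, :]) / d, 0.0, None)
    shat = (len(phis) - 1) * (wq @ q)
    return float(np.max(s - shat))


def beta_scan(
    G: GenotypeMatrix,
    panel: PopulationPanel,
    windows,
    d: float = 0.15,
    freq_bounds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Per-population beta-like scores per window, with Z-standardisation.

    SNPs with per-population frequency outside ``freq_bounds`` (before
    folding) are excluded; folded frequencies phi = min(p, 1-p) then lie in
    [0.1, 0.5]. Class proportions are estimated genome-wide per population.
    Windows with < 2 usable SNPs carry a missing score.
    """
    panel.validate_against(G)
    wf = windows if isinstance(windows, pd.DataFrame) else windows_frame(windows)
    widx = assign_sites_to_windows(G.sites, wf)
    lo, hi = freq_bounds
    records = []
    for pop in panel.pop_ids:
        rows = G.sample_indices(panel.samples_of_pop(pop))
        counts, n_chrom = G.allele_stats(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / n_chrom
        # integer-folded counts keep the filter and phi exactly symmetric
        # under ref/alt relabelling (p <-> 1-p)
        in_bounds = (counts >= lo * n_chrom - 1e-9) & (counts <= hi * n_chrom + 1e-9)
        usable = (n_chrom >= 4) & in_bounds & (widx >= 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.minimum(counts, n_chrom - counts) / n_chrom
        qprops = folded_class_proportions(phi[usable])
        order = np.argsort(widx[usable], kind="mergesort")
        w_sorted = widx[usable][order]
        phi_sorted = phi[usable][order]
        bounds = np.searchsorted(w_sorted, np.arange(len(wf) + 1))
        for w in range(len(wf)):
            sl = slice(bounds[w], bounds[w + 1])
            phis = phi_sorted[sl]
            beta = beta_like_score(phis, qprops, d=d) if len(phis) >= 2 else float("nan")
            records.append(
                (wf["contig"].iloc[w], int(wf["start"].iloc[w]), int(wf["end"].iloc[w]),
                 pop, len(phis), beta)
            )
    df = pd.DataFrame(records, columns=["contig", "start", "end", "pop", "n_snps", "beta"])
    df["excluded"] = ~np.isfinite(df["beta"])
    df = z_transform(df, value_col="beta", z_col="z_beta")
    return df.drop(columns=["excluded"])


# ---------------------------------------------------------------------------
# pool-level comparisons
# ---------------------------------------------------------------------------


def pool_correlation(pooled: pd.DataFrame, outlier_mask) -> dict:
    """Pearson correlation between pools, separately for outliers/background.

    ``pooled`` carries ``mean_z_A``/``mean_z_R`` per window; returns
    r and two-sided p (t transform) for the outlier windows and for the
    remaining genome.
    """
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    out = {}
    for label, mask in (("outlier", outlier_mask), ("background", ~outlier_mask)):
        a = pooled.loc[mask, "mean_z_A"].to_numpy(dtype=float)
        r_ = pooled.loc[mask, "mean_z_R"].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(r_)
        a, r_ = a[keep], r_[keep]
        if len(a) < 3:
            raise ValidationError(f"{label}: need >= 3 paired values")
        if a.std() == 0 or r_.std() == 0:
            raise ValidationError(f"{label}: zero variance in a pool")
        res = sps.pearsonr(a, r_)
        out[f"r_{label}"] = float(res.statistic)
        out[f"p_{label}"] = float(res.pvalue)
    return out


def pool_rank_test(values_anadromous, values_resident):
    """Two-sided Wilcoxon rank-sum between pools on window-level values.

    Windows are not independent observations; the result carries a caveat
    flag to that effect.
    """
    x = np.asarray(values_anadromous, dtype=float)
    y = np.asarray(values_resident, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 5 or len(y) < 5:
        raise ValidationError("need >= 5 windows per pool")
    res = sps.ranksums(x, y)
    return {"W": float(res.statistic), "p": float(res.pvalue),
            "caveat": "windows are not independent observations"}
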
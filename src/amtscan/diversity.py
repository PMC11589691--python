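"""Per-population folded site frequency spectra and windowed diversity.

Implements the classical frequency-spectrum summaries on called genotypes:
Watterson's theta (theta_W = S / (a1 L)), pairwise nucleotide diversity
(pi), Tajima's D with the 1989 normalisation constants, the folded SFS
(with hypergeometric down-projection when per-site sample sizes vary), an
EM estimator of the folded SFS from genotype likelihoods, and per-window
tracks with Z-standardised Tajima's D.

Missing genotypes are excluded per site: a site counts as segregating in a
population only if both alleles are observed among its non-missing calls.
Tajima's D is a missing value (NaN) when S = 0 or a window is excluded;
propagating NaN rather than zero keeps the Z-standardisation unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .core_io import (
    MISSING,
    GenotypeMatrix,
    PopulationPanel,
    ValidationError,
    assign_sites_to_windows,
    windows_frame,
)


# ---------------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------------


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum_{i<n} 1/i (power=1) or a2 = sum_{i<n} 1/i^2 (power=2)."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def theta_watterson(S: float, n: int, L: float) -> float:
    """Watterson's per-site estimate S / (a1 * L) for n chromosomes."""
    if n < 2:
        raise ValidationError("theta_watterson requires n >= 2 chromosomes")
    if L < 1:
        raise ValidationError("theta_watterson requires L >= 1")
    return S / (harmonic(n) * L)


def pi_from_counts(m, n, L: float) -> float:
    """Per-site pairwise diversity from minor counts m_i of n_i chromosomes.

    pi = (1/L) * sum_i 2 m_i (n_i - m_i) / (n_i (n_i - 1)).
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((m < 1) | (m > n - 1)):
        raise ValidationError("minor counts must satisfy 1 <= m <= n-1")
    return float(np.sum(2.0 * m * (n - m) / (n * (n - 1.0))) / L)


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D for S segregating sites and total pairwise diversity pi*L.

    Returns NaN for S = 0 (no information), raises for n < 4.
    """
    if n < 4:
        raise ValidationError("tajimas_d requires n >= 4 chromosomes")
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------


@dataclass
class FoldedSFS:
    """Folded spectrum: eta[k] is the mass at minor count k+1 (k = 0..n/2-1).

    ``eta`` may hold counts (from calls) or proportions (from EM); in the
    proportion case the monomorphic class absorbs the remainder.
    """

    n_chromosomes: int
    eta: np.ndarray
    n_sites_monomorphic: float = 0.0
    converged: bool = True

    def proportions(self) -> np.ndarray:
        total = self.eta.sum() + self.n_sites_monomorphic
        return self.eta / total if total > 0 else self.eta

    def count(self, m: int) -> float:
        """Mass at folded minor count m (1 <= m <= n/2)."""
        return float(self.eta[m - 1])


def folded_sfs_from_calls(G: GenotypeMatrix, samples=None, sites=None) -> FoldedSFS:
    """Folded SFS from called genotypes with hypergeometric projection.

    Per site, the minor count is folded from the dosage sum over non-missing
    calls. Sites whose non-missing chromosome count differs from the
    smallest common n are projected down to it by hypergeometric sampling
    (expected fractional class masses).
    """
    rows = None if samples is None else G.sample_indices(samples) if isinstance(samples[0], str) else np.asarray(samples)
    calls = G.calls if rows is None else G.calls[rows]
    if calls.shape[0] == 0:
        raise ValidationError("empty sample subset")
    if sites is not None:
        calls = calls[:, np.asarray(sites)]
    present = calls != MISSING
    counts = np.where(present, calls, 0).sum(axis=0).astype(np.int64)
    n_i = 2 * present.sum(axis=0).astype(np.int64)
    usable = n_i >= 2
    counts, n_i = counts[usable], n_i[usable]
    if counts.size == 0:
        return FoldedSFS(n_chromosomes=2 * calls.shape[0], eta=np.zeros(calls.shape[0]), n_sites_monomorphic=0.0)
    n_star = int(n_i.min())
    half = n_star // 2
    eta = np.zeros(half, dtype=float)
    mono = 0.0
    exact = n_i == n_star
    # exact-n sites: direct folding
    for j, n in zip(counts[exact], n_i[exact]):
        m = min(j, n - j)
        if m >= 1:
            eta[m - 1] += 1.0
        else:
            mono += 1.0
    # heterogeneous sites: project count j from n down to n_star
    for j, n in zip(counts[~exact], n_i[~exact]):
        k = np.arange(0, n_star + 1)
        pk = hypergeom.pmf(k, n, j, n_star)
        folded = np.minimum(k, n_star - k)
        mono += float(pk[folded == 0].sum())
        for m in range(1, half + 1):
            eta[m - 1] += float(pk[folded == m].sum())
    return FoldedSFS(n_chromosomes=n_star, eta=eta, n_sites_monomorphic=mono)


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def site_count_likelihoods(gl: np.ndarray) -> np.ndarray:
    """P(data | total alt count j) per site, via exchangeable DP convolution.

    ``gl`` has shape (n_sites, n_samples, 3): linear-scale likelihoods of
    genotypes (RR, RA, AA). Returns an array (n_sites, 2N+1) where column j
    is the probability of the per-sample read data given that the sample
    configuration was drawn uniformly among configurations with total alt
    count j (multivariate hypergeometric weighting).
    """
    gl = np.asarray(gl, dtype=float)
    n_sites, n_samples, _ = gl.shape
    if np.any(gl < 0) or np.any(gl.sum(axis=2) <= 0):
        raise ValidationError("genotype likelihood triples must be non-negative, not all zero")
    # DP over samples: h[:, j] = sum over configs of prod L_s(g_s) * C(2, g_s)
    h = np.zeros((n_sites, 2 * n_samples + 1))
    h[:, 0] = 1.0
    w = np.array([1.0, 2.0, 1.0])  # C(2, g)
    for s in range(n_samples):
        new = np.zeros_like(h)
        for g in range(3):
            new[:, g : g + 2 * s + 1] += h[:, : 2 * s + 1] * (gl[:, s, g] * w[g])[:, None]
        h = new
    j = np.arange(2 * n_samples + 1)
    return h / np.exp(_log_binom(2 * n_samples, j))[None, :]


def em_folded_sfs(gl: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> FoldedSFS:
    """EM estimate of the folded SFS from genotype likelihoods.

    E-step: per-site posterior over folded minor counts given the current
    spectrum prior and the per-sample likelihoods; M-step: the spectrum
    becomes the mean posterior. The log-likelihood is monotonically
    non-decreasing; non-convergence within ``max_iter`` sets
    ``converged=False`` on the result rather than raising.
    """
    lik = site_count_likelihoods(gl)  # (sites, 2N+1)
    n = lik.shape[1] - 1
    half = n // 2
    # folded class m is the even mixture of alt counts m and n-m: folding
    # carries no information on which orientation holds, so the class
    # likelihood is the average of the two (identity at m = n/2)
    fold_lik = np.zeros((lik.shape[0], half + 1))
    for m in range(half + 1):
        if m == n - m:
            fold_lik[:, m] = lik[:, m]
        else:
            fold_lik[:, m] = 0.5 * (lik[:, m] + lik[:, n - m])
    q = np.full(half + 1, 1.0 / (half + 1))
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        joint = fold_lik * q[None, :]
        site_tot = joint.sum(axis=1)
        ll = float(np.sum(np.log(site_tot)))
        if ll + 1e-12 < prev_ll:  # pragma: no cover - EM guarantee
            raise AssertionError("EM log-likelihood decreased")
        post = joint / site_tot[:, None]
        q_new = post.mean(axis=0)
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            converged = True
            break
        q = q_new
        prev_ll = ll
    return FoldedSFS(
        n_chromosomes=n,
        eta=q[1:],
        n_sites_monomorphic=float(q[0]),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------


def window_diversity_scan(
    G: GenotypeMatrix,
    panel: PopulationPanel,
    windows,
    min_sites: int = 500,
) -> pd.DataFrame:
    """Per population x window: L, S, theta_W, pi, Tajima's D.

    Windows with fewer than ``min_sites`` callable bases are flagged
    excluded and carry no Tajima's D. Per-site sample sizes are used
    exactly for pi; Tajima's D uses the modal non-missing chromosome
    count across the window's segregating sites.
    """
    panel.validate_against(G)
    wf = windows if isinstance(windows, pd.DataFrame) else windows_frame(windows)
    widx = assign_sites_to_windows(G.sites, wf)
    n_windows = len(wf)
    records = []
    for pop in panel.pop_ids:
        rows = G.sample_indices(panel.samples_of_pop(pop))
        counts, n_chrom = G.allele_stats(rows)
        m = np.minimum(counts, n_chrom - counts)
        seg = (counts > 0) & (counts < n_chrom) & (n_chrom >= 2)
        pi_site = np.zeros(len(counts))
        nn = n_chrom.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi_raw = 2.0 * counts * (n_chrom - counts) / (nn * (nn - 1.0))
        pi_site[seg] = pi_raw[seg]

        S = np.zeros(n_windows, dtype=np.int64)
        pi_total = np.zeros(n_windows)
        ok = widx >= 0
        np.add.at(S, widx[ok], seg[ok].astype(np.int64))
        np.add.at(pi_total, widx[ok], pi_site[ok])
        # modal non-missing chromosome count among segregating sites, per window
        n_modal = np.full(n_windows, 2 * len(rows), dtype=np.int64)
        seg_ok = seg & ok
        if seg_ok.any():
            mod = (
                pd.DataFrame({"w": widx[seg_ok], "n": n_chrom[seg_ok]})
                .groupby("w")["n"]
                .agg(lambda s: int(s.mode().iloc[0]))
            )
            n_modal[mod.index.to_numpy()] = mod.to_numpy()

        L_arr = wf["callable_sites"].to_numpy(dtype=np.int64)
        contigs = wf["contig"].to_numpy()
        starts = wf["start"].to_numpy()
        ends = wf["end"].to_numpy()
        for w in range(n_windows):
            L = int(L_arr[w])
            excluded = L < min_sites
            s_w = int(S[w])
            theta = theta_watterson(s_w, int(n_modal[w]), L) if L >= 1 else float("nan")
            pi = pi_total[w] / L if L >= 1 else float("nan")
            if excluded or s_w == 0:
                td = float("nan")
            else:
                td = tajimas_d(s_w, pi_total[w], int(n_modal[w]))
            records.append(
                (contigs[w], int(starts[w]), int(ends[w]), pop, L, s_w, theta, pi, td, excluded)
            )
    return pd.DataFrame(
        records,
        columns=["contig", "start", "end", "pop", "L", "S", "theta_w", "pi", "tajima_d", "excluded"],
    )


def z_transform(records: pd.DataFrame, value_col: str = "tajima_d", z_col: str = "z_td") -> pd.DataFrame:
    """Standardise a per-population window track to mean 0, sd 1.

    Computed per population over non-excluded windows with finite values;
    excluded/missing windows keep NaN. A degenerate (zero-sd) track raises.
    """
    out = records.copy()
    out[z_col] = np.nan
    for pop, grp in out.groupby("pop", sort=False):
        usable = (~grp["excluded"]) & np.isfinite(grp[value_col])
        vals = grp.loc[usable, value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValidationError(f"population {pop}: <2 usable windows for Z-transform")
        sd = vals.std()  # population sd
        if sd == 0:
            raise ValidationError(f"population {pop}: degenerate track (sd = 0)")
        out.loc[grp.index[usable], z_col] = (vals - vals.mean()) / sd
    return out
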
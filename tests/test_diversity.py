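"""Diversity statistics: frozen hand values, brute-force oracles, simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amtscan import core_io, diversity
from amtscan.synthetic_data import simulate_genotype_likelihoods

from conftest import make_genotypes, make_panel


# --------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# --------------------------------------------------------------------------


def oracle_pi_per_site(column):
    """Average pairwise difference at one site by explicit enumeration."""
    chroms = []
    for dosage in column:
        if dosage < 0:
            continue
        chroms += [1] * dosage + [0] * (2 - dosage)
    n = len(chroms)
    diffs = sum(
        1 for i in range(n) for j in range(i + 1, n) if chroms[i] != chroms[j]
    )
    return diffs / (n * (n - 1) / 2)


def oracle_tajimas_d(S, pi_total, n):
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


class TestScalarEstimators:
    def test_watterson_hand_value(self):
        # n=4: a1 = 1 + 1/2 + 1/3 = 1.833333
        assert diversity.theta_watterson(11, 4, 10_000) == pytest.approx(6.000e-4, rel=1e-4)

    def test_watterson_zero_s(self):
        assert diversity.theta_watterson(0, 10, 1_000) == 0.0

    def test_watterson_halves_when_length_doubles(self):
        assert diversity.theta_watterson(7, 12, 2_000) == pytest.approx(
            diversity.theta_watterson(7, 12, 1_000) / 2
        )

    def test_pi_hand_values(self):
        assert diversity.pi_from_counts([1], [2], 1) == pytest.approx(1.0)
        assert diversity.pi_from_counts([5], [10], 1) == pytest.approx(0.5556, abs=1e-4)
        assert diversity.pi_from_counts([], [], 1) == 0.0  # monomorphic window

    def test_pi_rejects_out_of_range_counts(self):
        with pytest.raises(core_io.ValidationError):
            diversity.pi_from_counts([0], [10], 1)

    def test_tajima_negative_for_all_singletons(self):
        # n=20, S=10 singletons: pi_total = 2S/n = 1.0 < S/a1
        assert diversity.tajimas_d(10, 1.0, 20) < 0

    def test_tajima_matches_bruteforce_oracle(self):
        expected = oracle_tajimas_d(16, 3.8889, 10)
        assert diversity.tajimas_d(16, 3.8889, 10) == pytest.approx(expected, rel=1e-12)

    def test_tajima_missing_when_no_segregating_sites(self):
        assert np.isnan(diversity.tajimas_d(0, 0.0, 10))

    def test_tajima_rejects_tiny_samples(self):
        with pytest.raises(core_io.ValidationError):
            diversity.tajimas_d(5, 1.0, 3)

    def test_tajima_centred_under_neutral_coalescent(self):
        # recombining windows: the single-genealogy skew of D (which gives
        # the statistic a noticeable negative mean at low rho) averages out
        import msprime

        vals = []
        for i in range(400):
            ts = msprime.sim_ancestry(
                samples=25, population_size=1_000, sequence_length=10_000,
                recombination_rate=1e-6, random_seed=10_000 + i,
            )
            ts = msprime.sim_mutations(
                ts, rate=1e-6, model=msprime.BinaryMutationModel(), random_seed=20_000 + i
            )
            G = ts.genotype_matrix()
            n = G.shape[1]
            counts = G.sum(axis=1)
            seg = (counts > 0) & (counts < n)
            S = int(seg.sum())
            if S == 0:
                continue
            c = counts[seg]
            pi_total = float(np.sum(2 * c * (n - c) / (n * (n - 1))))
            vals.append(diversity.tajimas_d(S, pi_total, n))
        assert abs(np.mean(vals)) < 0.1


class TestFoldedSFS:
    def test_singleton(self):
        G = make_genotypes([[1], [0], [0], [0]])
        sfs = diversity.folded_sfs_from_calls(G)
        assert sfs.count(1) == 1

    def test_folding_symmetry_of_high_count(self):
        # dosages (2,2,1,1): alt count 6 of n=8 -> folded class 2
        G = make_genotypes([[2], [2], [1], [1]])
        sfs = diversity.folded_sfs_from_calls(G)
        assert sfs.count(2) == 1

    def test_relabelling_ref_alt_leaves_sfs_unchanged(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        flipped = (2 - calls).astype(np.int8)
        a = diversity.folded_sfs_from_calls(make_genotypes(calls))
        b = diversity.folded_sfs_from_calls(make_genotypes(flipped))
        np.testing.assert_allclose(a.eta, b.eta)

    def test_hypergeometric_projection_hand_case(self):
        # site 1: count 4 of n=8, projected down to the smallest common n=6;
        # site 2: a missing call, count 1 of n=6 (no projection)
        calls = np.array([[1, 1], [1, 0], [1, 0], [1, -1]], dtype=np.int8)
        sfs = diversity.folded_sfs_from_calls(make_genotypes(calls))
        assert sfs.n_chromosomes == 6
        # hypergeometric draws of 6 from {4 alt, 4 ref}: P(k) = C(4,k)C(4,6-k)/C(8,6)
        # k=2: 6/28 (folds to 2), k=3: 16/28 (folds to 3), k=4: 6/28 (folds to 2)
        assert sfs.count(1) == pytest.approx(1.0)  # site 2 singleton
        assert sfs.count(2) == pytest.approx(12 / 28)
        assert sfs.count(3) == pytest.approx(16 / 28)
        assert sfs.n_sites_monomorphic == pytest.approx(0.0)

    def test_recovers_simulated_spectrum(self):
        rng = np.random.default_rng(99)
        n = 20  # chromosomes (10 diploids)
        true = np.array([1 / m for m in range(1, 11)])
        true = true / true.sum()
        m_draws = rng.choice(np.arange(1, 11), size=200, p=true)
        # build dosage columns with the drawn minor counts
        cols = []
        for m in m_draws:
            hap = np.zeros(n, dtype=int)
            hap[rng.choice(n, size=m, replace=False)] = 1
            cols.append(hap[::2] + hap[1::2])
        G = make_genotypes(np.array(cols).T)
        sfs = diversity.folded_sfs_from_calls(G)
        observed = sfs.eta
        expected = true * 200
        chi = sps.chisquare(observed, expected)
        assert chi.pvalue > 0.01


class TestEmFoldedSFS:
    def test_degenerate_likelihoods_equal_count_sfs(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        gl = np.zeros((60, 8, 3))
        for s in range(8):
            for g in range(3):
                gl[calls[s] == g, s, g] = 1.0
        em = diversity.em_folded_sfs(gl, max_iter=500, tol=1e-12)
        counted = diversity.folded_sfs_from_calls(make_genotypes(calls))
        total = counted.eta.sum() + counted.n_sites_monomorphic
        np.testing.assert_allclose(em.eta, counted.eta / total, atol=1e-6)

    def test_uninformative_likelihoods_keep_prior_fixed(self):
        gl = np.ones((1, 2, 3))
        # one EM step must return the (uniform) prior unchanged
        em = diversity.em_folded_sfs(gl, max_iter=1)
        np.testing.assert_allclose(
            np.concatenate([[em.n_sites_monomorphic], em.eta]), np.full(3, 1 / 3), atol=1e-12
        )

    def test_em_beats_naive_calling_on_noisy_data(self):
        rng = np.random.default_rng(17)
        n_samples, n_sites = 10, 500
        n = 2 * n_samples
        true_q = np.array([1 / m for m in range(1, n // 2 + 1)])
        true_q = np.concatenate([[2.0], true_q])  # monomorphic class
        true_q /= true_q.sum()
        counts = rng.choice(np.arange(0, n // 2 + 1), size=n_sites, p=true_q)
        genotypes = np.zeros((n_sites, n_samples), dtype=np.int64)
        for i, m in enumerate(counts):
            hap = np.zeros(n, dtype=int)
            hap[rng.choice(n, size=m, replace=False)] = 1
            genotypes[i] = hap[::2] + hap[1::2]
        gl = simulate_genotype_likelihoods(genotypes, mean_depth=5, error_rate=0.01, seed=23)

        em = diversity.em_folded_sfs(gl, max_iter=300)
        em_q = np.concatenate([[em.n_sites_monomorphic], em.eta])

        # naive route: per-sample maximum-likelihood genotype, then count
        called = gl.argmax(axis=2)
        naive_counts = np.minimum(called.sum(axis=1), n - called.sum(axis=1))
        naive_q = np.bincount(naive_counts, minlength=n // 2 + 1) / n_sites

        emp_q = np.bincount(counts, minlength=n // 2 + 1) / n_sites  # realised truth
        tv_em = 0.5 * np.abs(em_q - emp_q).sum()
        tv_naive = 0.5 * np.abs(naive_q - emp_q).sum()
        assert tv_em < tv_naive

    def test_loglikelihood_never_decreases(self):
        rng = np.random.default_rng(4)
        genotypes = rng.integers(0, 3, size=(80, 6))
        gl = simulate_genotype_likelihoods(genotypes, mean_depth=2, seed=8)
        lik = diversity.site_count_likelihoods(gl)
        n = lik.shape[1] - 1
        half = n // 2
        fold = np.zeros((lik.shape[0], half + 1))
        for m in range(half + 1):
            fold[:, m] = lik[:, m] if m == n - m else lik[:, m] + lik[:, n - m]
        q = np.full(half + 1, 1 / (half + 1))
        prev = -np.inf
        for _ in range(50):
            joint = fold * q
            tot = joint.sum(axis=1)
            ll = float(np.log(tot).sum())
            assert ll >= prev - 1e-9
            prev = ll
            q = (joint / tot[:, None]).mean(axis=0)


@pytest.fixture(scope="module")
def small_scan(small_dataset):
    windows = core_io.make_windows(small_dataset.contig_lengths, small_dataset.mask)
    div = diversity.window_diversity_scan(
        small_dataset.genotypes, small_dataset.panel, windows
    )
    return diversity.z_transform(div)


class TestWindowScan:
    def test_short_window_is_excluded(self):
        panel = make_panel(n_rivers=2, per_pop=3)
        calls = np.zeros((12, 2), dtype=np.int8)
        calls[0, :] = 1
        G = make_genotypes(calls, sample_ids=list(panel.table["sample"]))
        windows = [core_io.WindowSpec("chr1", 0, 10_000, 499)]
        div = diversity.window_diversity_scan(G, panel, windows, min_sites=500)
        assert div["excluded"].all()
        assert div["tajima_d"].isna().all()

    def test_invariant_window_has_zero_stats(self):
        panel = make_panel(n_rivers=2, per_pop=3)
        calls = np.zeros((12, 1), dtype=np.int8)
        calls[:6, 0] = 1  # segregating only on chr1 window 0
        G = make_genotypes(calls, positions=[5], sample_ids=list(panel.table["sample"]))
        windows = core_io.make_windows({"chr1": 20_000}, [("chr1", 0, 20_000)])
        div = diversity.window_diversity_scan(G, panel, windows, min_sites=500)
        empty = div[div["start"] == 10_000]
        assert (empty["S"] == 0).all()
        assert (empty["theta_w"] == 0).all()
        assert (empty["pi"] == 0).all()
        assert empty["tajima_d"].isna().all()

    def test_matches_site_by_site_bruteforce(self, small_dataset):
        ds = small_dataset
        windows = core_io.make_windows(ds.contig_lengths, ds.mask)[:4]
        div = diversity.window_diversity_scan(ds.genotypes, ds.panel, windows)
        pop = ds.panel.pop_ids[0]
        rows = ds.genotypes.sample_indices(ds.panel.samples_of_pop(pop))
        sub = ds.genotypes.calls[rows]
        for w in windows:
            in_w = (
                (ds.genotypes.sites["contig"] == w.contig)
                & (ds.genotypes.sites["pos"] >= w.start)
                & (ds.genotypes.sites["pos"] < w.end)
            ).to_numpy()
            S = 0
            pi_total = 0.0
            for j in np.flatnonzero(in_w):
                col = sub[:, j]
                present = col[col >= 0]
                n = 2 * len(present)
                c = present.sum()
                if 0 < c < n:
                    S += 1
                    pi_total += oracle_pi_per_site(col)
            rec = div[(div["pop"] == pop) & (div["start"] == w.start) & (div["contig"] == w.contig)].iloc[0]
            assert rec["S"] == S
            assert rec["pi"] == pytest.approx(pi_total / w.callable_sites, rel=1e-9)

    def test_resident_diversity_lower_and_tajima_higher(self, small_scan, small_config):
        g = small_scan[~small_scan["excluded"]].groupby("pop")[["theta_w", "tajima_d"]].mean()
        rivers = small_config.rivers
        theta_ok = sum(g.loc[f"{r}_R", "theta_w"] < g.loc[f"{r}_A", "theta_w"] for r in rivers)
        td_ok = sum(g.loc[f"{r}_R", "tajima_d"] > g.loc[f"{r}_A", "tajima_d"] for r in rivers)
        assert theta_ok >= 4
        assert td_ok >= 4


class TestZTransform:
    def _track(self, tds):
        return pd.DataFrame(
            {
                "contig": "chr1",
                "start": np.arange(len(tds)) * 10_000,
                "end": (np.arange(len(tds)) + 1) * 10_000,
                "pop": "CT_A",
                "tajima_d": tds,
                "excluded": False,
            }
        )

    def test_hand_values(self):
        z = diversity.z_transform(self._track([1.0, 2.0, 3.0]))["z_td"]
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_standardisation_property(self):
        rng = np.random.default_rng(2)
        z = diversity.z_transform(self._track(rng.normal(size=200)))["z_td"]
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z) == pytest.approx(1, abs=1e-12)

    def test_shift_invariance(self):
        vals = [0.3, -1.0, 2.2, 0.9]
        z1 = diversity.z_transform(self._track(vals))["z_td"]
        z2 = diversity.z_transform(self._track([v + 5.0 for v in vals]))["z_td"]
        np.testing.assert_allclose(z1, z2)

    def test_degenerate_track_rejected(self):
        with pytest.raises(core_io.ValidationError):
            diversity.z_transform(self._track([1.0, 1.0, 1.0]))
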
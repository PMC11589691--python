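"""Hudson F_ST, the whitened contrast statistic and POD calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amtscan import core_io, divergence

from conftest import make_genotypes, make_panel


class TestHudsonFstSite:
    def test_fixed_difference(self):
        num, den = divergence.hudson_fst_site(1.0, 10, 0.0, 10)
        assert (num, den) == (1.0, 1.0)

    def test_equal_frequencies_hand_value(self):
        num, den = divergence.hudson_fst_site(0.5, 10, 0.5, 10)
        assert num == pytest.approx(-0.05556, abs=1e-5)
        assert den == pytest.approx(0.5)

    def test_divergent_hand_value(self):
        num, den = divergence.hudson_fst_site(0.8, 40, 0.2, 40)
        assert num == pytest.approx(0.35179, abs=1e-5)
        assert den == pytest.approx(0.68)
        assert num / den == pytest.approx(0.5173, abs=1e-4)

    def test_rejects_single_chromosome(self):
        with pytest.raises(core_io.ValidationError):
            divergence.hudson_fst_site(0.5, 1, 0.5, 10)

    def test_group_label_swap_leaves_fst_unchanged(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(50), rng.random(50)
        n1, n2 = 20, 30
        a = divergence.hudson_fst_site(p1, n1, p2, n2)
        b = divergence.hudson_fst_site(p2, n2, p1, n1)
        np.testing.assert_allclose(a[0], b[0])
        np.testing.assert_allclose(a[1], b[1])


class TestFstWindowScan:
    def _setup(self, calls, positions=None):
        panel = make_panel(n_rivers=1, per_pop=len(calls) // 2)
        G = make_genotypes(calls, positions=positions, sample_ids=list(panel.table["sample"]))
        windows = core_io.make_windows({"chr1": 10_000}, [("chr1", 0, 10_000)])
        return G, panel, windows

    def test_all_fixed_differences_give_one(self):
        # A samples (rows 0,1 of each river block) homozygous minor, R major
        calls = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        G, panel, windows = self._setup(calls)
        rec = divergence.fst_window_scan(G, panel, windows, min_sites=1)
        assert rec["fst"].iloc[0] == pytest.approx(1.0)

    def test_matches_bruteforce_from_counts(self, small_dataset):
        ds = small_dataset
        windows = core_io.make_windows(ds.contig_lengths, ds.mask)[:3]
        rec = divergence.fst_window_scan(ds.genotypes, ds.panel, windows)
        G = ds.genotypes
        rows_a = G.sample_indices(ds.panel.samples_of_ecotype("A"))
        rows_r = G.sample_indices(ds.panel.samples_of_ecotype("R"))
        for w_i, w in enumerate(windows):
            num = den = 0.0
            for j in range(G.n_sites):
                site = G.sites.iloc[j]
                if not (site["contig"] == w.contig and w.start <= site["pos"] < w.end):
                    continue
                col_a = G.calls[rows_a, j]
                col_r = G.calls[rows_r, j]
                ca, cr = col_a[col_a >= 0], col_r[col_r >= 0]
                n1, n2 = 2 * len(ca), 2 * len(cr)
                p1, p2 = ca.sum() / n1, cr.sum() / n2
                d = p1 * (1 - p2) + p2 * (1 - p1)
                if d == 0:
                    continue
                num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
                den += d
            assert rec["fst"].iloc[w_i] == pytest.approx(num / den, rel=1e-9)

    def test_panmictic_split_centres_on_zero(self):
        import msprime

        rng = np.random.default_rng(8)
        fsts = []
        panel = make_panel(per_pop=10, rivers=["XX"])
        for i in range(60):
            ts = msprime.sim_ancestry(samples=20, population_size=1_000,
                                      sequence_length=10_000, random_seed=300 + i)
            ts = msprime.sim_mutations(ts, rate=5e-7, random_seed=700 + i)
            H = ts.genotype_matrix()
            dos = (H[:, ::2] + H[:, 1::2]).astype(np.int8).T  # (ind, sites)
            order = rng.permutation(20)
            calls = dos[order]
            G = make_genotypes(calls, positions=ts.tables.sites.position.astype(int),
                               sample_ids=list(panel.table["sample"]))
            windows = core_io.make_windows({"chr1": 10_000}, [("chr1", 0, 10_000)])
            rec = divergence.fst_window_scan(G, panel, windows, min_sites=1)
            fsts.append(rec["fst"].iloc[0])
        assert abs(np.nanmean(fsts)) < 0.01

    def test_ratio_of_sums_differs_from_mean_of_ratios(self):
        # one high-information site and one nearly-uninformative site
        p1 = np.array([0.9, 0.52])
        p2 = np.array([0.1, 0.48])
        num, den = divergence.hudson_fst_site(p1, 100, p2, 100)
        ratio_of_sums = num.sum() / den.sum()
        mean_of_ratios = np.mean(num / den)
        assert ratio_of_sums != pytest.approx(mean_of_ratios, rel=1e-3)


class TestFstOutliers:
    def _records(self, fsts):
        n = len(fsts)
        return pd.DataFrame(
            {"contig": "chr1", "start": np.arange(n) * 10_000, "end": (np.arange(n) + 1) * 10_000,
             "comparison": "global", "fst": fsts, "excluded": False}
        )

    def test_exact_top_percent_count(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.linspace(0, 1, 1_000))
        out, thr = divergence.fst_outliers(self._records(vals), quantile=0.99)
        assert len(out) == 10
        assert (out["fst"] >= thr).all()

    def test_ties_at_threshold_all_included(self):
        # the 99% quantile falls inside a block of 15 tied values: all come in
        vals = np.concatenate([np.linspace(0, 0.5, 985), np.full(15, 0.9)])
        out, thr = divergence.fst_outliers(self._records(vals), quantile=0.99)
        assert thr == pytest.approx(0.9)
        assert len(out) == 15
        assert (out["fst"] == 0.9).all()


class TestContrastModel:
    def test_identical_frequencies_give_ridge_omega(self):
        freqs = np.tile(np.linspace(0.1, 0.9, 200)[:, None], (1, 4))
        omega = divergence.estimate_pop_cov(freqs, epsilon=1e-3)
        np.testing.assert_allclose(omega, 1e-3 * np.eye(4), atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_omega_positive_definite(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.clip(rng.random((80, 6)), 0.01, 0.99)
        omega = divergence.estimate_pop_cov(freqs)
        np.linalg.cholesky(omega)  # raises if not PD

    def test_higher_drift_inflates_diagonal(self):
        # three demes drifting from a shared frequency, Ne 100 vs 1000 vs 1000
        rng = np.random.default_rng(21)
        n_snps, t = 2_000, 30
        p0 = rng.uniform(0.2, 0.8, size=n_snps)
        demes = [p0.copy(), p0.copy(), p0.copy()]
        sizes = [200, 2_000, 2_000]
        for _ in range(t):
            demes = [rng.binomial(n, p) / n for n, p in zip(sizes, demes)]
        freqs = np.stack(demes, axis=1)
        keep = (freqs.mean(axis=1) > 0) & (freqs.mean(axis=1) < 1)
        omega = divergence.estimate_pop_cov(freqs[keep])
        assert omega[0, 0] > omega[1, 1]
        assert omega[0, 0] > omega[2, 2]

    def _model(self, n_pops=4):
        c = np.array([0.5, 0.5, -0.5, -0.5])[:n_pops]
        return divergence.ContrastModel(
            pop_ids=[f"p{i}" for i in range(n_pops)], omega=np.eye(n_pops), epsilon=0.0, c=c
        )

    def test_no_contrast_gives_zero(self):
        model = self._model()
        assert divergence.contrast_stat(np.array([0.3, 0.3, 0.3, 0.3]), model) == pytest.approx(0.0)

    def test_hand_value(self):
        # pbar = 0.5 -> z = (1, 1, -1, -1); (c'z)^2 / c'Ic = 4 / 1
        model = self._model()
        stat = divergence.contrast_stat(np.array([1.0, 1.0, 0.0, 0.0]), model)
        assert stat == pytest.approx(4.0)

    def test_negating_contrast_vector_leaves_stat_unchanged(self):
        model = self._model()
        flipped = divergence.ContrastModel(model.pop_ids, model.omega, 0.0, -model.c)
        p = np.array([0.9, 0.4, 0.3, 0.2])
        assert divergence.contrast_stat(p, model) == pytest.approx(
            divergence.contrast_stat(p, flipped)
        )

    def test_neutral_mean_near_one(self):
        # exchangeable binomial drift around shared means -> chi2(1)-like stats
        rng = np.random.default_rng(31)
        n_snps, n_pops = 5_000, 10
        pbar = rng.uniform(0.1, 0.9, n_snps)
        freqs = rng.binomial(100, pbar[:, None].repeat(n_pops, 1)) / 100
        keep = (freqs.mean(axis=1) > 0) & (freqs.mean(axis=1) < 1)
        freqs = freqs[keep]
        omega = divergence.estimate_pop_cov(freqs)
        c = np.array([1 / 5] * 5 + [-1 / 5] * 5)
        model = divergence.ContrastModel([f"p{i}" for i in range(10)], omega, 1e-3, c)
        stats = divergence.contrast_stat(freqs, model)
        assert np.nanmean(stats) == pytest.approx(1.0, abs=0.1)


class TestPodThreshold:
    # scaled identity: a realistic drift scale keeps the frequency
    # reconstruction away from the clipping boundaries, where the
    # whitened contrast is chi-square(1) in closed form
    _SIGMA = 0.2

    def _identity_model(self):
        c = np.array([np.sqrt(0.5), -np.sqrt(0.5), 0.0, 0.0])
        return divergence.ContrastModel(
            ["a", "b", "c", "d"], self._SIGMA**2 * np.eye(4), 0.0, c
        )

    def test_scaled_identity_limit_matches_chi2_quantile(self):
        model = self._identity_model()
        rng = np.random.default_rng(5)
        pbar = rng.uniform(0.2, 0.8, 5_000)
        thr = divergence.pod_threshold(model, pbar, n_chrom=np.full(4, 400), n_pods=20_000, seed=2)
        assert thr == pytest.approx(6.63, abs=0.5)

    def test_threshold_stable_across_seeds(self):
        model = self._identity_model()
        rng = np.random.default_rng(6)
        pbar = rng.uniform(0.2, 0.8, 5_000)
        t1 = divergence.pod_threshold(model, pbar, np.full(4, 100), n_pods=10_000, seed=11)
        t2 = divergence.pod_threshold(model, pbar, np.full(4, 100), n_pods=10_000, seed=12)
        assert abs(t1 - t2) / t1 < 0.05

    def test_self_calibration_flags_one_percent(self):
        model = self._identity_model()
        rng = np.random.default_rng(7)
        pbar_pool = rng.uniform(0.2, 0.8, 5_000)
        thr = divergence.pod_threshold(model, pbar_pool, np.full(4, 100), n_pods=10_000, seed=3)
        # fresh neutral PODs drawn the same way
        pbar = rng.choice(pbar_pool, 20_000)
        z = rng.standard_normal((20_000, 4)) * self._SIGMA
        p = np.clip(pbar[:, None] + z * np.sqrt(pbar * (1 - pbar))[:, None], 1 / 200, 1 - 1 / 200)
        stats = divergence.contrast_stat(p, model)
        rate = np.mean(stats[np.isfinite(stats)] >= thr)
        assert rate == pytest.approx(0.01, abs=0.003)

    def test_too_few_pods_rejected(self):
        with pytest.raises(core_io.ValidationError):
            divergence.pod_threshold(self._identity_model(), np.array([0.5]), np.full(4, 100), n_pods=50)


class TestAmtIntersection:
    def _windows(self):
        return pd.DataFrame(
            {"contig": ["chr1", "chr1"], "start": [0, 10_000], "end": [10_000, 20_000],
             "fst": [0.5, 0.4], "excluded": [False, False]}
        )

    def test_no_significant_snps_gives_empty_set(self):
        snps = pd.DataFrame({"contig": ["chr1"], "pos": [5], "stat": [1.0], "significant": [False]})
        out = divergence.intersect_amt_outliers(self._windows(), snps)
        assert len(out.amt_windows) == 0

    def test_snp_at_window_end_goes_to_next_window(self):
        snps = pd.DataFrame(
            {"contig": ["chr1"], "pos": [10_000], "stat": [9.0], "significant": [True]}
        )
        out = divergence.intersect_amt_outliers(self._windows(), snps)
        assert list(out.amt_windows["start"]) == [10_000]

    def test_amt_subset_of_fst_outliers(self, small_run):
        _, results = small_run
        fst = core_io.read_track(results / "fst_windows.tsv")
        amt = core_io.read_track(results / "amt_windows.tsv")
        fst_keys = set(zip(fst["contig"], fst["start"]))
        assert all((c, s) in fst_keys for c, s in zip(amt["contig"], amt["start"]))
        assert len(amt) <= (~fst["excluded"]).sum()
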
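"""Gamma-DFE model, MCMC behaviour, alpha, and expression stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from homeopop import dfe, prf, simulate
from homeopop.dfe import DFEModel


def model(J=9, **kw):
    args = dict(shape=0.5, mean_gamma=10.0, theta_s=100.0, theta_n=300.0,
                r=np.ones(J))
    args.update(kw)
    return DFEModel(**args)


class TestExpectedSFS:
    def test_neutral_mean_gamma_reduces_to_harmonic(self, quad18):
        lam_s, lam_n = dfe.expected_sfs(model(mean_gamma=0.0), 18, quad18)
        neutral = dfe._folded_neutral(18)
        assert np.allclose(lam_n, 300.0 * neutral)

    def test_synonymous_classes_are_harmonic_when_r_is_one(self, quad18):
        lam_s, _ = dfe.expected_sfs(model(), 18, quad18)
        assert np.allclose(lam_s, 100.0 * dfe._folded_neutral(18))

    def test_nuisance_multipliers_scale_both_classes(self, quad18):
        r = np.concatenate([[1.0], np.full(8, 2.0)])
        lam_s1, lam_n1 = dfe.expected_sfs(model(), 18, quad18)
        lam_s2, lam_n2 = dfe.expected_sfs(model(r=r), 18, quad18)
        assert np.allclose(lam_s2[1:] / lam_s1[1:], 2.0)
        assert np.allclose(lam_n2[1:] / lam_n1[1:], 2.0)

    def test_r1_fixed_at_one(self):
        with pytest.raises(ValueError):
            model(r=np.full(9, 2.0))


class TestLoglik:
    def test_empty_sfs_is_minus_total_rate(self, quad18):
        m = model()
        zeros = np.zeros(9)
        lam_s, lam_n = dfe.expected_sfs(m, 18, quad18)
        assert dfe.loglik(m, zeros, zeros, 18, quad18) == \
            pytest.approx(-(lam_s.sum() + lam_n.sum()))

    def test_expectation_is_local_maximum(self, quad18):
        m = model()
        lam_s, lam_n = dfe.expected_sfs(m, 18, quad18)
        ll0 = dfe.loglik(m, lam_s, lam_n, 18, quad18)
        for factor in (0.7, 1.4):
            worse = model(theta_s=100.0 * factor, theta_n=300.0 * factor)
            assert dfe.loglik(worse, lam_s, lam_n, 18, quad18) < ll0

    def test_doubling_theta_s_lowers_likelihood_of_matched_data(self, quad18):
        m = model()
        lam_s, lam_n = dfe.expected_sfs(m, 18, quad18)
        doubled = model(theta_s=200.0)
        assert dfe.loglik(doubled, lam_s, lam_n, 18, quad18) < \
            dfe.loglik(m, lam_s, lam_n, 18, quad18)

    def test_order_invariance_is_bit_identical(self, quad18):
        """Summing classes in a fixed order: permuting data classes back
        and forth cannot change the result."""
        m = model()
        ks = np.arange(1, 10.0)
        kn = np.arange(2, 11.0)
        assert dfe.loglik(m, ks.copy(), kn.copy(), 18, quad18) == \
            dfe.loglik(m, ks[::-1][::-1], kn[::-1][::-1], 18, quad18)

    def test_zero_rate_with_observed_count_rejected(self, quad18):
        # theta_n small enough that some class rates underflow to exactly 0
        m = model(theta_n=1e-323)
        ks = np.ones(9)
        assert dfe.loglik(m, ks, ks, 18, quad18) == -np.inf


class TestMCMC:
    def test_zero_length_chain_is_an_error(self):
        with pytest.raises(ValueError, match="chain too short"):
            dfe.run_mcmc(np.ones(9), np.ones(9), 18, reps=100, thin=200,
                         burn=50)

    def test_two_seeds_agree_on_category_posteriors(self, quad18):
        """Gelman-Rubin over two chains with different seeds < 1.1."""
        sc = simulate.simulate_selected_counts(
            0.005, 18, 0.3, 100.0, 0.0, Ls=3e5, Ln=1e6, rng=5, quad=quad18)
        ks = prf.fold_expected(sc.sfs_syn, 18)
        kn = prf.fold_expected(sc.sfs_nonsyn, 18)
        mats = []
        for seed in (1, 2):
            post = dfe.run_mcmc(ks, kn, 18, reps=60_000, thin=100,
                                seed=seed, quad=quad18, site_ratio=10 / 3)
            mats.append(post.category_matrix())
        m = min(len(x) for x in mats)
        for cat in range(4):
            rhat = dfe.gelman_rubin([mats[0][:m, cat], mats[1][:m, cat]])
            assert rhat < 1.1

    def test_posterior_predictive_consistency(self, quad18):
        """Expected SFS at the posterior mean within ~3 Poisson sd of the
        observed counts on well-specified data."""
        sc = simulate.simulate_selected_counts(
            0.005, 18, 0.3, 100.0, 0.0, Ls=3e5, Ln=1e6, rng=7, quad=quad18)
        ks = prf.fold_expected(sc.sfs_syn, 18)
        kn = prf.fold_expected(sc.sfs_nonsyn, 18)
        post = dfe.run_mcmc(ks, kn, 18, reps=60_000, thin=100, seed=1,
                            quad=quad18, site_ratio=10 / 3)
        mean = post.samples.mean()
        r = np.concatenate([[1.0],
                            [mean[f"r_{j}"] for j in range(2, 10)]])
        m = DFEModel(mean["shape"], mean["mean_gamma"], mean["theta_s"],
                     mean["theta_n"], r)
        lam_s, lam_n = dfe.expected_sfs(m, 18, quad18)
        for k, lam in ((ks, lam_s), (kn, lam_n)):
            z = (k - lam) / np.sqrt(np.maximum(lam, 1.0))
            assert np.all(np.abs(z) < 4.0)

    def test_neutral_data_sanity(self, quad18):
        """Neutral syn + nonsyn spectra: posterior mass effectively
        neutral and the alpha interval covers 0."""
        sc = simulate.simulate_selected_counts(
            0.005, 18, 0.3, 0.0, 0.0, Ls=3e5, Ln=1e6, rng=2, quad=quad18)
        ks = prf.fold_expected(sc.sfs_syn, 18)
        kn = prf.fold_expected(sc.sfs_nonsyn, 18)
        post = dfe.run_mcmc(ks, kn, 18, reps=250_000, thin=100, burn=50_000,
                            seed=3, quad=quad18, site_ratio=10 / 3)
        cats = dfe.nes_categories(post)
        assert cats["mean"][0] >= 0.9
        al = dfe.estimate_alpha(post, sc.Dn, sc.Ds, sc.Ln, sc.Ls)
        assert al["ci_low"] <= 0.0 <= al["ci_high"]


class TestCategoriesAndAlpha:
    def test_category_proportions_sum_to_one_per_sample(self, quad18):
        samples = pd.DataFrame({
            "shape": [0.3, 0.5, 1.0], "mean_gamma": [100.0, 5.0, 0.01],
            "theta_s": [1, 1, 1.0], "theta_n": [1, 1, 1.0]})
        post = dfe.DFEPosterior(18, samples, 0.3, quad18)
        mat = post.category_matrix()
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_alpha_zero_for_neutral_dfe_with_matched_divergence(self, quad18):
        samples = pd.DataFrame({
            "shape": [0.5], "mean_gamma": [1e-9],
            "theta_s": [1.0], "theta_n": [3.0]})
        post = dfe.DFEPosterior(18, samples, 0.3, quad18)
        out = dfe.estimate_alpha(post, Dn=300, Ds=100, Ln=3000, Ls=1000)
        assert out["alpha"] == pytest.approx(0.0, abs=1e-6)

    def test_alpha_approaches_one_in_strong_deleterious_limit(self, quad18):
        samples = pd.DataFrame({
            "shape": [2.0], "mean_gamma": [1e5],
            "theta_s": [1.0], "theta_n": [3.0]})
        post = dfe.DFEPosterior(18, samples, 0.3, quad18)
        out = dfe.estimate_alpha(post, Dn=300, Ds=100, Ln=3000, Ls=1000)
        assert out["alpha"] > 0.99

    def test_alpha_absent_without_nonsyn_divergence(self, quad18):
        samples = pd.DataFrame({"shape": [0.5], "mean_gamma": [1.0],
                                "theta_s": [1.0], "theta_n": [1.0]})
        post = dfe.DFEPosterior(18, samples, 0.3, quad18)
        assert dfe.estimate_alpha(post, 0, 100, 1000, 1000) is None


class TestStratification:
    def test_uniform_rpkm_ties_break_by_gene_id(self):
        genes = [f"g{i:02d}" for i in range(20)]
        out = dfe.stratify_by_expression(genes, [1.0] * 20, q=0.10)
        assert out["high"] == ["g00", "g01"]
        assert out["low"] == ["g00", "g01"]

    def test_half_split_partitions_gene_list(self):
        genes = [f"g{i}" for i in range(10)]
        rpkm = list(range(10))
        out = dfe.stratify_by_expression(genes, rpkm, q=0.5)
        assert sorted(out["high"] + out["low"]) == sorted(genes)
        assert set(out["high"]).isdisjoint(out["low"])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            dfe.stratify_by_expression(["a"], [1.0], q=0.1)

    def test_stronger_selection_in_high_stratum_recovered(self, quad18):
        """Two-truth simulation: the 'high' stratum is fit with a lower
        neutral proportion than the 'low' stratum."""
        sc_hi = simulate.simulate_selected_counts(
            0.005, 18, 0.3, 500.0, 0.0, Ls=2e5, Ln=6e5, rng=3, quad=quad18)
        sc_lo = simulate.simulate_selected_counts(
            0.005, 18, 0.3, 0.5, 0.0, Ls=2e5, Ln=6e5, rng=4, quad=quad18)
        neutral = {}
        for name, sc in (("high", sc_hi), ("low", sc_lo)):
            post = dfe.run_mcmc(prf.fold_expected(sc.sfs_syn, 18),
                                prf.fold_expected(sc.sfs_nonsyn, 18),
                                18, reps=60_000, thin=100, seed=6,
                                quad=quad18, site_ratio=3.0)
            neutral[name] = dfe.nes_categories(post)["mean"][0]
        assert neutral["high"] < neutral["low"]


class TestSubsample:
    def test_identity_at_full_size(self):
        items = list("abcdef")
        assert dfe.subsample_accessions(items, 6, seed=1) == items

    def test_reproducible_and_uniform(self):
        items = list(range(25))
        a = dfe.subsample_accessions(items, 18, seed=9)
        b = dfe.subsample_accessions(items, 18, seed=9)
        assert a == b and len(set(a)) == 18

    def test_subsampled_sfs_matches_projection_expectation(self, rng):
        """Mean subsampled SFS over repeats ~ hypergeometric projection."""
        from homeopop.popgen import SiteFrequencySpectrum, project_sfs
        n, m = 10, 6
        counts = np.array([30, 20, 10, 5, 5, 3, 2, 1, 1.0])
        sfs = SiteFrequencySpectrum(counts, n, folded=False)
        proj = project_sfs(sfs, m)
        acc = np.zeros(m - 1)
        R = 400
        for _ in range(R):
            for i, c in enumerate(counts, start=1):
                for _ in range(int(c)):
                    keep = rng.choice(n, size=m, replace=False)
                    d = (keep < i).sum()
                    if 0 < d < m:
                        acc[d - 1] += 1
        acc /= R
        assert np.allclose(acc, proj.counts, atol=3 * np.sqrt(counts.sum()
                                                              / R))

    def test_oversample_rejected(self):
        with pytest.raises(ValueError):
            dfe.subsample_accessions([1, 2], 3)
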
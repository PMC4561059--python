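"""GRM construction, relatedness pruning, REML, scale conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famscan as fs
from famscan.greml import _restricted_loglik

from conftest import make_genotypes


def _unrelated_sample(seed, n=400, m=600, h2=0.4):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.5, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    Z = (dos - dos.mean(axis=0)) / np.sqrt(2 * p * (1 - p))
    u = rng.normal(0, np.sqrt(h2 / m), m)
    y = Z @ u + rng.normal(0, np.sqrt(1 - h2), n)
    return make_genotypes(dos, mafs=p), y


class TestGRM:
    def test_hand_evaluated_entries(self):
        # one SNP, sample frequency 0.5: pair (2, 0) -> (1)(-1)/0.5 = -2
        grm = fs.compute_grm(make_genotypes([[2], [0]]))
        assert grm.values[0, 1] == pytest.approx(-2.0)
        assert grm.values[0, 0] == pytest.approx(2.0)

    def test_heterozygote_diagonal_contribution_zero(self):
        # at p = 0.5 the centered heterozygote dosage is 0
        grm = fs.compute_grm(make_genotypes([[1], [1], [2], [0]]))
        assert grm.values[0, 0] == pytest.approx(0.0)

    def test_mean_diagonal_near_one_under_hwe(self):
        geno, _ = _unrelated_sample(0, n=300, m=2000)
        grm = fs.compute_grm(geno)
        assert grm.values.diagonal().mean() == pytest.approx(1.0, abs=0.02)

    def test_invariant_to_allele_label_flip(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (50, 30))
        a = fs.compute_grm(make_genotypes(dos))
        b = fs.compute_grm(make_genotypes(2 - dos))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_monomorphic_snps_skipped(self):
        dos = np.column_stack([np.ones(20, dtype=int) * 2,
                               np.random.default_rng(2).integers(0, 3, 20)])
        grm = fs.compute_grm(make_genotypes(dos))
        assert grm.n_snps_used == 1

    def test_round_trip_through_gcta_triplets(self, tmp_path):
        geno, _ = _unrelated_sample(3, n=25, m=40)
        grm = fs.compute_grm(geno)
        fs.write_grm(grm, str(tmp_path / "test"))
        back = fs.read_grm(str(tmp_path / "test"))
        assert back.ids == grm.ids
        np.testing.assert_allclose(back.values, grm.values, atol=1e-6)


class TestPruneRelated:
    def _grm(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        ids = ids or [chr(65 + i) for i in range(len(values))]
        return fs.GRM(ids=ids, values=values, n_snps_used=1)

    def test_all_unrelated_all_retained(self):
        g = self._grm(np.eye(4) + 0.01 - 0.01 * np.eye(4))
        assert fs.prune_related(g) == ["A", "B", "C", "D"]

    def test_one_close_pair_drops_exactly_one(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.5
        assert len(fs.prune_related(self._grm(v))) == 2

    def test_greedy_removes_the_hub(self):
        # A-B = 0.3, B-C = 0.3, A-C = 0.01: dropping B suffices
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.3
        v[1, 2] = v[2, 1] = 0.3
        v[0, 2] = v[2, 0] = 0.01
        assert fs.prune_related(self._grm(v)) == ["A", "C"]


class TestREML:
    def test_matches_grid_search_oracle_on_small_sample(self):
        geno, y = _unrelated_sample(4, n=150, m=300)
        grm = fs.compute_grm(geno)
        fit = fs.REML(compute_lrt=False).fit(y, grms=[grm])
        # independent direct search over the (sigma_g, sigma_e) plane
        vp = np.var(y, ddof=1)
        X = np.ones((len(y), 1))
        best = -np.inf
        for fg in np.linspace(0.001, 0.999, 120):
            for s in (0.8 * vp, 0.9 * vp, vp, 1.1 * vp, 1.2 * vp):
                ll = _restricted_loglik(np.array([fg * s, (1 - fg) * s]),
                                        y, X, [grm.values])[0]
                best = max(best, ll)
        assert fit.loglik_ >= best - 1e-4

    def test_parameter_recovery(self):
        geno, y = _unrelated_sample(5, n=500, m=800, h2=0.4)
        vc = fs.reml_fit(y, grms=[fs.compute_grm(geno)])
        assert abs(float(vc.h2_obs) - 0.4) < 3 * float(vc.h2_se)

    def test_null_phenotype_piles_on_zero_boundary(self):
        """With no genetic signal a sizable share of REML fits hits the
        zero boundary of the genetic variance."""
        rng = np.random.default_rng(6)
        geno, _ = _unrelated_sample(7, n=80, m=150)
        grm = fs.compute_grm(geno)
        zeros = 0
        ests = []
        for _ in range(60):
            y = rng.normal(size=80)
            fit = fs.REML(compute_lrt=False).fit(y, grms=[grm])
            ests.append(fit.sigma2_[0])
            zeros += fit.sigma2_[0] == 0.0
        assert zeros >= 10
        assert np.median(ests) < 0.3

    def test_two_component_partitioning_consistency(self):
        rng = np.random.default_rng(8)
        n, m = 500, 500
        p = rng.uniform(0.05, 0.5, 2 * m)
        dos = rng.binomial(2, p, size=(n, 2 * m)).astype(np.int8)
        Z = (dos - dos.mean(axis=0)) / np.sqrt(2 * p * (1 - p))
        u = np.concatenate([rng.normal(0, np.sqrt(0.15 / m), m),
                            rng.normal(0, np.sqrt(0.10 / m), m)])
        y = Z @ u + rng.normal(0, np.sqrt(0.75), n)
        geno = make_genotypes(dos, mafs=p)
        g1 = fs.compute_grm(geno, snp_mask=np.arange(2 * m) < m)
        g2 = fs.compute_grm(geno, snp_mask=np.arange(2 * m) >= m)
        fit = fs.REML(compute_lrt=False).fit(y, grms=[g1, g2])
        h2 = np.asarray(fit.h2_obs_)
        se = np.asarray(fit.h2_se_)
        assert abs(h2[0] - 0.15) < 3 * se[0]
        assert abs(h2[1] - 0.10) < 3 * se[1]
        total = fs.REML(compute_lrt=False).fit(y, grms=[fs.compute_grm(geno)])
        assert abs(h2.sum() - float(total.h2_obs_)) < 3 * np.hypot(*se)

    def test_lrt_significant_under_signal(self):
        geno, y = _unrelated_sample(9, n=500, m=800, h2=0.5)
        vc = fs.reml_fit(y, grms=[fs.compute_grm(geno)])
        assert vc.lrt > 0
        assert vc.p < 0.05


class TestScaleAndRegression:
    def test_mixture_lrt_pvalues(self):
        assert fs.lrt_mixture_pvalue(0.0) == pytest.approx(0.5)
        # half the chi-square(1) tail: reproduces the printed P = 0.0016
        assert fs.lrt_mixture_pvalue(8.60) == pytest.approx(0.00168, abs=1e-5)
        assert fs.lrt_mixture_pvalue(2.706) == pytest.approx(0.05, abs=1e-4)
        with pytest.raises(ValueError):
            fs.lrt_mixture_pvalue(-1.0)

    def test_observed_to_liability(self):
        assert fs.observed_to_liability(0.0, 0.22) == 0.0
        # K = 1/2: threshold 0, phi(0)^2 = 1/(2 pi), factor = pi/2
        assert fs.observed_to_liability(0.2, 0.5) == pytest.approx(0.2 * np.pi / 2)
        # numeric normal quantile/density oracle
        z = stats.norm.ppf(1 - 0.22)
        expected = 0.25 * 0.22 * 0.78 / stats.norm.pdf(z) ** 2
        assert fs.observed_to_liability(0.25, 0.22) == pytest.approx(expected)
        assert fs.observed_to_liability(0.25, 0.22) == pytest.approx(0.49, abs=0.01)
        with pytest.raises(ValueError):
            fs.observed_to_liability(0.2, 1.0)

    def test_chromosome_length_regression_perfect_fit(self):
        L = np.linspace(5e7, 2.5e8, 22)
        slope, t, p = fs.chromosome_length_regression(0.01 * L / L.mean(), L)
        assert p < 1e-10

    def test_one_tailed_p_for_printed_t_statistic(self):
        # construct 22 points whose realized slope t equals 1.731 exactly,
        # then the one-tailed p on 20 df must be 0.0494 (< 0.05)
        rng = np.random.default_rng(10)
        L = np.linspace(5e7, 2.5e8, 22)
        r = rng.normal(size=22)
        X = np.column_stack([np.ones(22), L])
        r = r - X @ np.linalg.lstsq(X, r, rcond=None)[0]  # residualize
        slope_target = 1e-10
        Lc = L - L.mean()
        # t = slope / (s * sqrt(1/Sxx)) with s^2 = ||r||^2 scale / 20
        sxx = float(Lc @ Lc)
        scale = slope_target * np.sqrt(sxx) * np.sqrt(20) / (1.731 * np.linalg.norm(r))
        v = slope_target * L + scale * r
        slope, t, p = fs.chromosome_length_regression(v, L)
        assert t == pytest.approx(1.731, abs=1e-6)
        assert p == pytest.approx(0.0494, abs=1e-4)
        assert p < 0.05

    def test_null_regression_p_uniform(self):
        rng = np.random.default_rng(11)
        L = np.linspace(5e7, 2.5e8, 22)
        pvals = [fs.chromosome_length_regression(rng.normal(size=22), L)[2]
                 for _ in range(300)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_lengths_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fs.chromosome_length_regression([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
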
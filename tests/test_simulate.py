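"""Family simulator: structures, Mendelian genotypes, liability, onset."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famscan as fs


def couples_mixture(n):
    return fs.FamilyMixture(n_families=n, proportions={(0, 2): 1.0})


def sibpair_mixture(n):
    return fs.FamilyMixture(n_families=n, proportions={(2, 0): 1.0})


# ---------------------------------------------------------------------------
# family structures
# ---------------------------------------------------------------------------

class TestStructures:
    def test_default_mixture_counts(self, default_pedigree):
        ped = default_pedigree
        assert ped.n_families == 3690
        # expected total individuals ~6,700 under the default mixture
        assert 6400 <= len(ped.table) <= 7050
        sizes = ped.table.groupby("family_id").size()
        assert sizes.min() >= 1 and sizes.max() <= 8

    def test_expected_individuals_property(self):
        assert fs.FamilyMixture().expected_individuals == pytest.approx(6725, abs=15)

    def test_degenerate_singleton_mixture(self):
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=10, proportions={(0, 1): 1.0}), seed=3)
        assert ped.n_families == 10 and len(ped.table) == 10

    def test_same_seed_identical(self):
        a = fs.sample_family_structures(seed=5)
        b = fs.sample_family_structures(seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_mixtures_rejected(self):
        with pytest.raises(ValueError):
            fs.FamilyMixture(proportions={(0, 1): 0.5})  # does not sum to 1
        with pytest.raises(ValueError):
            fs.FamilyMixture(proportions={(9, 2): 1.0})  # unsupported sibship


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

class TestGenotypes:
    def test_founder_maf_and_hwe(self):
        # 25,000 couples -> 50,000 founder genotypes
        ped = fs.sample_family_structures(couples_mixture(25_000), seed=7)
        geno = fs.simulate_genotypes(ped, causal_maf=0.5, seed=8)
        g = geno.dosages[:, 0]
        assert g.mean() / 2 == pytest.approx(0.5, abs=0.005)
        counts = [(g == k).sum() for k in (0, 1, 2)]
        assert fs.hwe_chisq_pvalue(*counts) > 1e-3

    def test_sib_dosage_correlation_matches_mendelian_oracle(self):
        # oracle: enumerate parental genotypes (HWE) and transmissions
        def oracle_corr(p):
            probs = {g: c for g, c in zip(
                (0, 1, 2), ((1 - p) ** 2, 2 * p * (1 - p), p**2))}
            joint = {}
            for gf, pf in probs.items():
                for gm, pm in probs.items():
                    # allele from a parent with genotype g is Bernoulli(g/2)
                    for a1 in (0, 1):
                        for b1 in (0, 1):
                            for a2 in (0, 1):
                                for b2 in (0, 1):
                                    pr = (pf * pm
                                          * (gf / 2 if a1 else 1 - gf / 2)
                                          * (gm / 2 if b1 else 1 - gm / 2)
                                          * (gf / 2 if a2 else 1 - gf / 2)
                                          * (gm / 2 if b2 else 1 - gm / 2))
                                    key = (a1 + b1, a2 + b2)
                                    joint[key] = joint.get(key, 0.0) + pr
            e1 = sum(k[0] * v for k, v in joint.items())
            e2 = sum(k[1] * v for k, v in joint.items())
            cov = sum(k[0] * k[1] * v for k, v in joint.items()) - e1 * e2
            var = sum(k[0] ** 2 * v for k, v in joint.items()) - e1**2
            return cov / var

        for p in (0.5, 0.2):
            assert oracle_corr(p) == pytest.approx(0.5, abs=1e-12)

        ped = fs.sample_family_structures(sibpair_mixture(30_000), seed=9)
        geno = fs.simulate_genotypes(ped, causal_maf=0.3, seed=10)
        g = geno.dosages[:, 0].reshape(-1, 2)
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=3 * (1 - 0.25) / np.sqrt(30_000))

    def test_null_snps_independent_without_ld(self):
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=4000, proportions={(0, 1): 1.0}), seed=11)
        geno = fs.simulate_genotypes(ped, n_null_snps=12, ld_block_corr=0.0, seed=12)
        r = np.corrcoef(geno.dosages[:, 1:].T.astype(float))
        off = r[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 4 / np.sqrt(4000)

    def test_ld_blocks_have_positive_adjacent_correlation(self):
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=4000, proportions={(0, 1): 1.0}), seed=13)
        geno = fs.simulate_genotypes(ped, n_null_snps=10, ld_block_corr=0.7,
                                     ld_block_size=5, seed=14)
        dos = geno.dosages[:, 1:].astype(float)
        adj_in_block = [np.corrcoef(dos[:, j], dos[:, j + 1])[0, 1]
                        for j in (0, 1, 2, 3)]
        across = np.corrcoef(dos[:, 4], dos[:, 5])[0, 1]
        # the copula's latent correlation (0.7) attenuates on the dosage
        # scale, more so for low-MAF SNPs
        assert min(adj_in_block) > 0.25
        assert abs(across) < 0.12


# ---------------------------------------------------------------------------
# liability
# ---------------------------------------------------------------------------

class TestLiability:
    def test_null_effect_no_association(self):
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=5000, proportions={(0, 1): 1.0}), seed=15)
        geno = fs.simulate_genotypes(ped, seed=16)
        ph = fs.simulate_liability(ped, geno, fs.LiabilityParams(q2=0.0), seed=17)
        r = stats.pointbiserialr(ph["initiated"], geno.dosages[:, 0]).statistic
        assert abs(r) < 4 / np.sqrt(5000)

    def test_prevalence_matches_normal_tail(self):
        # analytic check: 1 - Phi(0.85) = 0.1977
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=55_000), seed=18)
        ph = fs.simulate_liability(ped, seed=19)
        target = stats.norm.sf(0.85)
        n = len(ph)
        se = np.sqrt(target * (1 - target) / n)
        # familial clustering inflates the effective SE; allow 5 nominal SEs
        assert ph["initiated"].mean() == pytest.approx(target, abs=5 * se)

    def test_relative_pair_correlations_recovered(self):
        params = fs.LiabilityParams()
        for mixture, expected, n in [(couples_mixture(20_000), params.r_spouse, 20_000),
                                     (sibpair_mixture(20_000), params.r_sib, 20_000)]:
            ped = fs.sample_family_structures(mixture, seed=20)
            ph = fs.simulate_liability(ped, params=params, seed=21)
            liab = ph["liability"].to_numpy().reshape(-1, 2)
            r = np.corrcoef(liab[:, 0], liab[:, 1])[0, 1]
            se = (1 - expected**2) / np.sqrt(n)
            assert r == pytest.approx(expected, abs=3 * se)

    def test_parent_offspring_correlation_recovered(self):
        mixture = fs.FamilyMixture(n_families=20_000, proportions={(1, 1): 1.0})
        ped = fs.sample_family_structures(mixture, seed=22)
        ph = fs.simulate_liability(ped, seed=23)
        liab = ph["liability"].to_numpy().reshape(-1, 2)
        r = np.corrcoef(liab[:, 0], liab[:, 1])[0, 1]
        se = (1 - 0.15**2) / np.sqrt(20_000)
        assert r == pytest.approx(0.15, abs=3 * se)

    def test_variance_bookkeeping(self):
        # R^2 of liability on causal dosage equals q2
        q2 = 0.015
        ped = fs.sample_family_structures(
            fs.FamilyMixture(n_families=30_000, proportions={(0, 1): 1.0}), seed=24)
        geno = fs.simulate_genotypes(ped, causal_maf=0.5, seed=25)
        ph = fs.simulate_liability(ped, geno, fs.LiabilityParams(q2=q2), seed=26)
        r = np.corrcoef(ph["liability"], geno.dosages[:, 0])[0, 1]
        assert r**2 == pytest.approx(q2, abs=3 * 2 * np.sqrt(q2) / np.sqrt(30_000))

    def test_deterministic_given_seed(self, toy_pedigree):
        a = fs.simulate_liability(toy_pedigree, seed=1)
        b = fs.simulate_liability(toy_pedigree, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_non_positive_definite_family_matrix_reported(self):
        mixture = fs.FamilyMixture(n_families=5, proportions={(3, 0): 1.0})
        ped = fs.sample_family_structures(mixture, seed=27)
        with pytest.raises(ValueError, match="3 sibs"):
            fs.simulate_liability(ped, params=fs.LiabilityParams(r_sib=-0.8), seed=28)


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------

class TestOnset:
    def test_event_fraction_calibration(self):
        ped = fs.sample_family_structures(fs.FamilyMixture(n_families=2750), seed=29)
        ph = fs.simulate_liability(ped, seed=30)
        surv = fs.simulate_onset(ped, None, ph, seed=31)
        assert surv["event"].mean() == pytest.approx(0.166, abs=0.015)
        # consistency invariants
        ev = surv["event"] == 1
        assert (surv.loc[ev, "onset_age"] <= surv.loc[ev, "observation_age"]).all()
        assert surv.loc[~ev, "onset_age"].isna().all()
        assert (surv["initiated"] == surv["event"]).all()

    def test_null_genotype_effect_gives_unit_hazard_ratio(self):
        ped = fs.sample_family_structures(fs.FamilyMixture(n_families=2750), seed=32)
        geno = fs.simulate_genotypes(ped, seed=33)
        ph = fs.simulate_liability(ped, geno, seed=34)
        surv = fs.simulate_onset(ped, geno, ph, fs.OnsetParams(beta_g=0.0), seed=35)
        keep = np.isin(np.asarray(geno.individuals), surv["individual_id"])
        g = geno.dosages[keep, 0].astype(float)
        t = np.where(surv["event"] == 1, surv["onset_age"], surv["observation_age"])
        fit = fs.CoxPH().fit(g[:, None], t, surv["event"].to_numpy(),
                             clusters=surv["family_id"].to_numpy())
        assert abs(fit.coef_[0]) < 3 * fit.robust_se_[0] + 1e-9

    def test_degenerate_censoring_gives_zero_events(self):
        ped = fs.sample_family_structures(fs.FamilyMixture(n_families=200), seed=36)
        ph = fs.simulate_liability(ped, seed=37)
        params = fs.OnsetParams(censor_mean=5.0, censor_sd=0.5, censor_min=1.0,
                                min_onset_age=10.0)
        surv = fs.simulate_onset(ped, None, ph, params, seed=38)
        assert surv["event"].sum() == 0

    def test_onsets_at_or_below_minimum_age_excluded(self):
        ped = fs.sample_family_structures(fs.FamilyMixture(n_families=3000), seed=39)
        ph = fs.simulate_liability(ped, seed=40)
        surv = fs.simulate_onset(ped, None, ph, seed=41)
        assert (surv["onset_age"].dropna() > 10.0).all()
        assert len(surv) < len(ph)  # some early onsets were excluded
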
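"""Tests of the cohort/genotype/exposure/trajectory simulator."""

import numpy as np
import pandas as pd
import pytest

from gefam.cohort_sim import (
    InteractionMatrix,
    ScenarioConfig,
    generate_cohort,
    interaction_preset,
    scenario_preset,
    simulate_cohort_data,
    simulate_environment,
    simulate_genotypes,
    simulate_trajectories,
)


class TestGenerateCohort:
    def test_default_study_size_is_788_individuals(self):
        cohort = generate_cohort(168, 226, seed=0)
        assert cohort.n_individuals == 788
        assert (cohort.zygosity == "MZ").sum() == 168
        assert (cohort.zygosity == "DZ").sum() == 226

    def test_empty_cohort_is_valid(self):
        cohort = generate_cohort(0, 0, seed=0)
        assert cohort.n_individuals == 0
        assert cohort.individuals_frame().empty

    def test_skeleton_invariants(self):
        cohort = generate_cohort(50, 50, seed=1)
        mz = cohort.zygosity == "MZ"
        assert (cohort.sex[mz, 0] == cohort.sex[mz, 1]).all()
        assert (cohort.visit_ages[:, 0] == 0).all()
        assert (np.diff(cohort.visit_ages, axis=1) > 0).all()

    def test_visit2_age_matches_sampling_distribution(self):
        # 1000 MZ pairs: mean of visit-2 ages within 3 SE of 6.28
        cohort = generate_cohort(1000, 0, seed=7)
        assert (cohort.sex[:, 0] == cohort.sex[:, 1]).all()
        ages2 = cohort.visit_ages[:, 1]
        se = 0.74 / np.sqrt(1000)
        assert abs(ages2.mean() - 6.28) < 3 * se

    def test_rejects_nonincreasing_age_means(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_cohort(5, 5, visit_age_means=(0, 10, 5, 20, 30, 40),
                            visit_age_sds=(0,) * 6, seed=0)


class TestSimulateGenotypes:
    def test_maf_zero_gives_all_common_homozygotes(self):
        cohort = generate_cohort(10, 10, seed=0)
        geno = simulate_genotypes(cohort, maf=0.0, seed=1)
        assert (geno.child == 0).all()

    def test_hardy_weinberg_frequencies(self):
        # random mating + Mendelian transmission -> HW proportions
        cohort = generate_cohort(0, 20000, seed=3)
        geno = simulate_genotypes(cohort, maf=0.3, seed=4)
        g = geno.child[:, 0]  # one child per family: independent draws
        freqs = np.bincount(g, minlength=3) / len(g)
        expected = np.array([0.49, 0.42, 0.09])
        se = np.sqrt(expected * (1 - expected) / len(g))
        assert np.all(np.abs(freqs - expected) < 4 * se)

    def test_twin_genotype_sharing(self):
        cohort = generate_cohort(5000, 5000, seed=5)
        geno = simulate_genotypes(cohort, maf=0.3, seed=6)
        mz = cohort.zygosity == "MZ"
        assert (geno.child[mz, 0] == geno.child[mz, 1]).all()
        dz = geno.child[~mz]
        r = np.corrcoef(dz[:, 0], dz[:, 1])[0, 1]
        assert abs(r - 0.5) < 0.05  # sib allele-sharing expectation

    def test_mendelian_consistency_with_parents(self):
        cohort = generate_cohort(200, 200, seed=8)
        geno = simulate_genotypes(cohort, maf=0.4, seed=9)
        # child count must be attainable as one allele from each parent
        for parent in (geno.maternal, geno.paternal):
            low = np.where(parent == 2, 1, 0)
            high = np.where(parent == 0, 0, 1)
            for m in range(2):
                other = geno.maternal if parent is geno.paternal else geno.paternal
                olow = np.where(other == 2, 1, 0)
                ohigh = np.where(other == 0, 0, 1)
                assert (geno.child[:, m] >= low + olow).all()
                assert (geno.child[:, m] <= high + ohigh).all()


class TestSimulateEnvironment:
    def test_degenerate_frequencies(self):
        cohort = generate_cohort(10, 10, seed=0)
        assert (simulate_environment(cohort, 1.0, seed=1) == 1).all()
        assert (simulate_environment(cohort, 0.0, seed=1) == 0).all()

    def test_exposure_frequency_and_pair_independence(self):
        cohort = generate_cohort(5000, 5000, seed=2)
        env = simulate_environment(cohort, 0.3, seed=3)
        n = env.size
        assert abs(env.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)
        r = np.corrcoef(env[:, 0], env[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(env.shape[0])


class TestInteractionPresets:
    def test_linear_is_multiplicative(self):
        m = interaction_preset("linear")
        assert m[2, 1] == 2
        assert (m.m[:, 0] == 0).all()
        for g in range(3):
            for e in range(2):
                assert m[g, e] == g * e

    def test_xor_contrast_is_orthogonal_to_additive_coding(self):
        # the exposure contrast delta(g) carries no weighted-linear signal
        # at HW(0.3), so a multiplicative GxE term cannot represent it
        m = interaction_preset("xor")
        w = np.array([0.49, 0.42, 0.09])
        g = np.array([0.0, 1.0, 2.0])
        delta = m.m[:, 1] - m.m[:, 0]
        gbar = (w * g).sum()
        cov = (w * delta * g).sum() - (w * delta).sum() * gbar
        assert abs(cov) < 1e-12
        # but the contrast itself is far from additive in g (non-linear)
        assert np.ptp(delta) > 1
        assert np.abs(m.m).max() <= 2

    def test_xor_flips_the_affected_genotype_with_exposure(self):
        m = interaction_preset("xor")
        assert np.argmax(m.m[:, 0]) != np.argmax(m.m[:, 1])

    def test_other_presets(self):
        cd = interaction_preset("conditional_dominant")
        assert list(cd.m[:, 0]) == [0, 1, 2]  # additive unexposed
        assert list(cd.m[:, 1]) == [0, 2, 2]  # dominant (plateau) exposed
        sm = interaction_preset("small_marginal")
        assert sm.m.sum() == 1 and sm[2, 1] == 1  # recessive, exposure-only

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="linear"):
            interaction_preset("quadratic")


class TestScenarioPresets:
    def test_null_change_environment_scaling(self):
        sc = scenario_preset("null_change", beta_gt=0.015)
        assert sc.beta_E == pytest.approx(0.6)

    def test_null_average_zero_is_pure_noise(self):
        sc = scenario_preset("null_average", beta_g=0.0)
        assert sc.beta_G == sc.beta_E == sc.beta_GE == sc.beta_GTE == 0

    def test_ge_linear_fixed_parameters(self):
        sc = scenario_preset("ge_linear", beta_ge=0.5)
        assert sc.beta_G == 0.25 and sc.beta_E == 0.5
        assert sc.beta_GT == 0 and sc.beta_GTE == 0
        assert sc.interaction.name == "linear"
        assert (sc.beta_0, sc.beta_S, sc.beta_T, sc.beta_Tp) == (11, 0.5, 0.8, -0.8)
        assert (sc.sigma2_A, sc.sigma2_C, sc.sigma2_E) == (3, 1.5, 1.5)
        assert sc.tau2_A == sc.tau2_C == 0.001

    def test_off_grid_knob_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            scenario_preset("ge_linear", beta_ge=0.55)

    def test_channel_consistency_enforced(self):
        with pytest.raises(ValueError):
            ScenarioConfig(effect_channel="average", beta_GE=0.0)


class TestSimulateTrajectories:
    def test_deterministic_collapse(self):
        sc = ScenarioConfig(
            beta_S=0, beta_T=0, beta_Tp=0, sigma2_A=0, sigma2_C=0,
            tau2_A=0, tau2_C=0, sigma2_E=0,
        )
        cohort = generate_cohort(3, 3, seed=0)
        geno = simulate_genotypes(cohort, 0.3, seed=1)
        env = simulate_environment(cohort, 0.3, seed=2)
        rec = simulate_trajectories(cohort, geno, env, sc, seed=3)
        assert np.allclose(rec["bmi"], 11.0)

    def test_segmented_time_rule_by_visit_index(self):
        # beta_Tp acts only after visit 2, as T - 6
        base = ScenarioConfig(
            beta_S=0, beta_T=0, beta_Tp=0, sigma2_A=0, sigma2_C=0,
            tau2_A=0, tau2_C=0, sigma2_E=0,
        )
        with_tp = base.replace(beta_Tp=1.0)
        cohort = generate_cohort(2, 2, seed=4)
        geno = simulate_genotypes(cohort, 0.3, seed=1)
        env = simulate_environment(cohort, 0.3, seed=2)
        r0 = simulate_trajectories(cohort, geno, env, base, seed=3)
        r1 = simulate_trajectories(cohort, geno, env, with_tp, seed=3)
        diff = r1["bmi"] - r0["bmi"]
        early = r1["visit"] <= 2
        assert np.allclose(diff[early], 0)
        assert np.allclose(diff[~early], r1.loc[~early, "age_months"] - 6.0)

    def test_intercept_pair_correlations(self):
        # with only intercept variance left, Y = beta_0 + C0
        sc = ScenarioConfig(
            beta_S=0, beta_T=0, beta_Tp=0, tau2_A=0, tau2_C=0, sigma2_E=0
        )
        cohort = generate_cohort(3000, 3000, seed=10)
        geno = simulate_genotypes(cohort, 0.3, seed=1)
        env = simulate_environment(cohort, 0.3, seed=2)
        rec = simulate_trajectories(cohort, geno, env, sc, seed=11)
        first = rec[rec["visit"] == 1]
        y = first.set_index("individual_id")["bmi"]
        ids = cohort.individual_ids
        y1, y2 = y[ids[:, 0]].to_numpy(), y[ids[:, 1]].to_numpy()
        mz = cohort.zygosity == "MZ"
        r_mz = np.corrcoef(y1[mz], y2[mz])[0, 1]
        r_dz = np.corrcoef(y1[~mz], y2[~mz])[0, 1]
        assert r_mz == pytest.approx(1.0, abs=1e-10)
        assert r_dz == pytest.approx(2 / 3, abs=0.03)  # (1.5+1.5)/4.5

    def test_marginal_variance_at_birth(self):
        sc = scenario_preset("null_average", beta_g=0.0)
        cohort = generate_cohort(4000, 4000, seed=12)
        geno = simulate_genotypes(cohort, 0.3, seed=1)
        env = simulate_environment(cohort, 0.3, seed=2)
        rec = simulate_trajectories(cohort, geno, env, sc, seed=13)
        birth = rec[rec["visit"] == 1]
        one_per_fam = birth.groupby("family_id")["bmi"].first()
        v = one_per_fam.var(ddof=1)
        n = len(one_per_fam)
        se = 6.0 * np.sqrt(2 / (n - 1))
        assert abs(v - 6.0) < 3 * se  # sigma2_A + sigma2_C + sigma2_E

    def test_moments_match_generating_model(self):
        # fixed visit schedule; residual moments over 200 small cohorts
        sc = scenario_preset("null_average", beta_g=0.5)
        ages = np.array([0.0, 6.28, 19.49, 31.77, 49.85, 62.25])
        resids = []
        for r in range(200):
            cohort = generate_cohort(
                25, 25, visit_age_sds=(0,) * 6, seed=100 + r
            )
            geno = simulate_genotypes(cohort, sc.maf, seed=200 + r)
            env = simulate_environment(cohort, sc.exposure_freq, seed=300 + r)
            rec = simulate_trajectories(cohort, geno, env, sc, seed=400 + r)
            tp = np.where(rec["visit"] <= 2, 0.0, rec["age_months"] - 6.0)
            det = (
                sc.beta_0
                + sc.beta_S * (rec["sex"] == "M")
                + sc.beta_T * rec["age_months"]
                + sc.beta_Tp * tp
                + sc.beta_G * rec["genotype"]
                + sc.beta_E * rec["exposure"]
            )
            rec = rec.assign(resid=rec["bmi"] - det)
            resids.append(rec[["visit", "resid"]])
        allr = pd.concat(resids)
        for k, age in enumerate(ages, start=1):
            r = allr.loc[allr["visit"] == k, "resid"].to_numpy()
            var_exp = 4.5 + age**2 * 0.002 + 1.5
            assert abs(r.mean()) < 3 * np.sqrt(var_exp / len(r))
            assert abs(r.var(ddof=1) - var_exp) < 3 * var_exp * np.sqrt(
                2 / (len(r) - 1)
            )

    def test_seed_determinism(self):
        sc = scenario_preset("ge_linear", beta_ge=0.3)
        _, _, _, r1 = simulate_cohort_data(sc, seed=99)
        _, _, _, r2 = simulate_cohort_data(sc, seed=99)
        pd.testing.assert_frame_equal(r1, r2)

    def test_dropout_removes_rows(self):
        sc = scenario_preset("null_average", beta_g=0.0).replace(
            dropout_prob=0.3, n_mz_pairs=100, n_dz_pairs=100
        )
        _, _, _, rec = simulate_cohort_data(sc, seed=5)
        assert len(rec) < 200 * 2 * 6
        assert len(rec) > 0.5 * 200 * 2 * 6

    def test_interaction_matrix_validation(self):
        with pytest.raises(ValueError, match="3x2"):
            InteractionMatrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="finite"):
            InteractionMatrix(np.array([[0, np.inf]] * 3))
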
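"""Tests of the ACE twin path model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gefam._inference import lr_test, wald_test
from gefam import twin_model
from gefam.twin_model import ace_loglik, fit_twin_model, test_effect as effect_test


def _pair_frame(y, zygosity):
    """Summaries-like frame of complete pairs with trivial covariates."""
    y = np.asarray(y, dtype=float)
    n_pairs = len(y) // 2
    return pd.DataFrame(
        {
            "individual_id": np.arange(len(y)),
            "family_id": np.repeat(np.arange(n_pairs), 2),
            "zygosity": np.repeat(zygosity, 2),
            "sex": ["F", "M"] * n_pairs,
            "genotype": (np.arange(len(y)) % 3).astype(float),
            "exposure": ((np.arange(len(y)) // 2) % 2).astype(float),
            "mean_bmi": y,
            "mean_age": 28.0 + 0.1 * np.arange(len(y)),
            "n_visits": 6,
        }
    )


class TestAceLoglik:
    def test_standard_normal_pair(self):
        # a=c=0, e=1, beta=0, y=(0,0): two independent standard normals
        frame = _pair_frame([0.0, 0.0], ["MZ"])
        ll = ace_loglik((np.array([0.0]), 0.0, 0.0, 1.0), frame)
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_matches_dense_multivariate_normal(self):
        # 3-pair toy vs direct matrix-form density evaluation
        rng = np.random.default_rng(11)
        y = rng.normal(1.0, 2.0, 6)
        zyg = ["MZ", "DZ", "MZ"]
        frame = _pair_frame(y, zyg)
        a, c, e, mu = 1.3, 0.7, 0.9, 1.1
        ll = ace_loglik((np.array([mu]), a, c, e), frame)
        v = a**2 + c**2 + e**2
        oracle = 0.0
        for i, z in enumerate(zyg):
            w = a**2 + c**2 if z == "MZ" else 0.5 * a**2 + c**2
            cov = np.array([[v, w], [w, v]])
            oracle += stats.multivariate_normal.logpdf(
                y[2 * i:2 * i + 2], mean=[mu, mu], cov=cov
            )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_singleton_contributes_univariate_margin(self):
        frame = _pair_frame([0.5, -0.5], ["DZ"]).iloc[:1]
        ll = ace_loglik((np.array([0.0]), 0.0, 0.0, 1.0), frame)
        assert ll == pytest.approx(stats.norm.logpdf(0.5), abs=1e-12)


class TestFitTwinModel:
    def test_parameter_recovery_pair_level(self):
        # simulate directly at the pair level with a2=3, c2=1.5, e2=1.5
        rng = np.random.default_rng(21)
        a2s, c2s, e2s = [], [], []
        for _ in range(60):
            n_mz, n_dz = 120, 120
            rows = []
            for z, n in (("MZ", n_mz), ("DZ", n_dz)):
                # sib additive-genetic values: corr 1 (MZ) or 0.5 (DZ)
                g1 = rng.normal(0, np.sqrt(3.0), n)
                g2 = g1 if z == "MZ" else 0.5 * g1 + rng.normal(
                    0, np.sqrt(3.0 * 0.75), n
                )
                cshare = rng.normal(0, np.sqrt(1.5), n)
                y1 = g1 + cshare + rng.normal(0, np.sqrt(1.5), n)
                y2 = g2 + cshare + rng.normal(0, np.sqrt(1.5), n)
                rows.append((z, y1, y2))
            y = np.concatenate(
                [np.column_stack([r[1], r[2]]).ravel() for r in rows]
            )
            zyg = [rows[0][0]] * n_mz + [rows[1][0]] * n_dz
            frame = _pair_frame(y, zyg)
            fit = fit_twin_model(frame, interaction=False)
            a2s.append(fit.a2)
            c2s.append(fit.c2)
            e2s.append(fit.e2)
        for est, truth in ((a2s, 3.0), (c2s, 1.5), (e2s, 1.5)):
            est = np.asarray(est)
            mc_se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * mc_se

    def test_no_familial_correlation_drives_a2_c2_to_zero(self):
        # shuffling outcomes across families removes all familial
        # correlation, so the familial components hit the zero boundary
        from gefam.cohort_sim import scenario_preset, simulate_cohort_data
        from gefam.prep import mean_over_time

        sc = scenario_preset("null_average", beta_g=0.0).replace(
            n_mz_pairs=200, n_dz_pairs=200
        )
        _, _, _, rec = simulate_cohort_data(sc, seed=31)
        summ = mean_over_time(rec)
        rng = np.random.default_rng(31)
        summ["mean_bmi"] = rng.permutation(summ["mean_bmi"].to_numpy())
        fit = fit_twin_model(summ)
        assert fit.a2 + fit.c2 < 0.15 * fit.total_variance

    def test_codominant_nests_additive(self, small_cohort_data):
        summ = small_cohort_data["summaries"]
        add = fit_twin_model(summ, genetic_coding="additive")
        cod = fit_twin_model(summ, genetic_coding="codominant")
        assert cod.loglik >= add.loglik - 1e-6

    def test_total_variance_tracks_empirical(self, small_cohort_data):
        summ = small_cohort_data["summaries"]
        fit = fit_twin_model(summ)
        emp = summ["mean_bmi"].var(ddof=1)
        assert fit.total_variance == pytest.approx(emp, rel=0.35)

    def test_invariant_to_family_and_member_order(self, small_cohort_data):
        summ = small_cohort_data["summaries"]
        fit1 = fit_twin_model(summ)
        shuffled = summ.sample(frac=1, random_state=3).reset_index(drop=True)
        fit2 = fit_twin_model(shuffled)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        fe1 = fit1.fixed_effects.set_index("term")["estimate"]
        fe2 = fit2.fixed_effects.set_index("term")["estimate"]
        assert fe1["G:E"] == pytest.approx(fe2["G:E"], abs=1e-4)

    def test_summary_frame_contains_variance_block(self, small_cohort_data):
        fit = fit_twin_model(small_cohort_data["summaries"])
        sf = fit.summary_frame()
        assert {"a2", "c2", "e2", "loglik"} <= set(sf["term"])


class TestTestEffect:
    def test_wald_basic_values(self):
        assert wald_test(0.0, 0.5)[1] == pytest.approx(1.0)
        assert wald_test(1.96, 1.0)[1] == pytest.approx(0.05, abs=1e-3)

    def test_lrt_chi_square_tail(self):
        stat, p = lr_test(-100.0, -103.0, df=2)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(np.exp(-3.0), abs=1e-6)  # chi2_2 tail

    def test_codominant_interaction_uses_2df_lrt(self, small_cohort_data):
        fit = fit_twin_model(
            small_cohort_data["summaries"], genetic_coding="codominant"
        )
        res = effect_test(fit, "G:E")
        assert res.kind == "lrt" and res.df == 2
        assert 0.0 <= res.p_value <= 1.0

    def test_unknown_term_rejected(self, small_cohort_data):
        fit = fit_twin_model(small_cohort_data["summaries"])
        with pytest.raises(KeyError):
            effect_test(fit, "no_such_term")
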
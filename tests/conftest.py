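"""Shared fixtures: small cohorts and the session-level Monte-Carlo runs.

The expensive simulation studies (type-I error, parameter recovery, PBI
null behavior, power orderings) are computed once per session and shared
by the tests that assert on different aspects of the same runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gefam import lmm, pbi, study, twin_model
from gefam.cohort_sim import scenario_preset, simulate_cohort_data
from gefam.prep import mean_over_time

ALPHA = 0.05


@pytest.fixture(scope="session")
def small_cohort_data():
    """One small simulated cohort (20 MZ + 30 DZ pairs) under a null."""
    sc = scenario_preset("null_average", beta_g=0.5).replace(
        n_mz_pairs=20, n_dz_pairs=30
    )
    cohort, geno, env, rec = simulate_cohort_data(sc, seed=424242)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summ = mean_over_time(rec)
    return {"scenario": sc, "cohort": cohort, "genotypes": geno,
            "environments": env, "records": rec, "summaries": summ}


@pytest.fixture(scope="session")
def null_interaction_run():
    """1000 null-interaction cohorts (beta_G=0.5, beta_E=1.0, beta_GE=0).

    Per replicate: twin-model and LMM G:E p-values (default analysis
    settings) plus, for the first 500 replicates, LMM fixed-effect
    estimates under the exactly-specified segmented basis and the twin
    sex estimate — the parameter-recovery material. Also pools genotype
    and exposure frequencies across cohorts.
    """
    sc = scenario_preset("null_average", beta_g=0.5)
    n_reps, n_recover = 1000, 500
    p_twin, p_lmm = [], []
    est = {"b0": [], "bS": [], "bT": [], "twin_bS": []}
    allele_count = total_alleles = 0
    exposed = total_ind = 0
    for r in range(n_reps):
        cohort, geno, env, rec = simulate_cohort_data(sc, seed=1000 + r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = mean_over_time(rec)
        tfit = twin_model.fit_twin_model(summ)
        p_twin.append(twin_model.test_effect(tfit, "G:E").p_value)
        lfit = lmm.fit_lmm(rec, test_target="GE")
        p_lmm.append(lmm.test_effect(lfit, "G:E").p_value)
        allele_count += int(geno.child[:, 0].sum())
        total_alleles += 2 * cohort.n_families
        exposed += int(env.sum())
        total_ind += env.size
        if r < n_recover:
            rfit = lmm.fit_lmm(rec, test_target="GE", time_basis="visit_rule")
            fe = rfit.fixed_effects.set_index("term")["estimate"]
            est["b0"].append(fe["intercept"])
            est["bS"].append(fe["sex"])
            est["bT"].append(fe["T"])
            tfe = tfit.fixed_effects.set_index("term")["estimate"]
            est["twin_bS"].append(tfe["sex"])
    return {
        "p_twin": np.array(p_twin),
        "p_lmm": np.array(p_lmm),
        "estimates": {k: np.array(v) for k, v in est.items()},
        "maf_hat": allele_count / total_alleles,
        "exposure_hat": exposed / total_ind,
        "n_reps": n_reps,
    }


@pytest.fixture(scope="session")
def pbi_noise_run():
    """PBI p-values over 500 pure-noise cohorts (no main effects)."""
    sc = scenario_preset("null_average", beta_g=0.0)
    p = [
        study.run_replicate(sc, methods=("pbi",), seed=3000 + r,
                            n_permutations=1000)["pbi"]
        for r in range(500)
    ]
    return np.array(p)


@pytest.fixture(scope="session")
def pbi_plateau_run():
    """PBI p-values over 300 null-GTE cohorts on the inflation plateau
    (beta_GT=0.02, beta_E=0.8, no interaction)."""
    sc = scenario_preset("null_change", beta_gt=0.02)
    p = [
        study.run_replicate(sc, methods=("pbi",), seed=5000 + r,
                            n_permutations=1000)["pbi"]
        for r in range(300)
    ]
    return np.array(p)


@pytest.fixture(scope="session")
def power_ordering_run():
    """Rejection proportions at R=500: linear GE (beta_GE=0.5) and the
    non-linear XOR pattern at the largest effect (beta_GE=1.0), for the
    twin model and the PBI test."""
    out = {}
    sc_lin = scenario_preset("ge_linear", beta_ge=0.5)
    tab = study.estimate_power(
        sc_lin, methods=("twin", "pbi"), n_replicates=500, alpha=ALPHA,
        base_seed=7000, n_permutations=1000,
    )
    out["linear"] = tab.set_index("method")["rejection_proportion"].to_dict()
    sc_xor = scenario_preset("ge_nonlinear", beta_ge=1.0, interaction="xor")
    tab = study.estimate_power(
        sc_xor, methods=("twin", "pbi"), n_replicates=500, alpha=ALPHA,
        base_seed=8000, n_permutations=1000,
    )
    out["xor"] = tab.set_index("method")["rejection_proportion"].to_dict()
    return out
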
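"""Experiment orchestration: replicate runs, power/type-I-error tables,
and the real-data-style gene-environment scan with Bonferroni reporting.

A replicate simulates one cohort under a scenario and applies the three
methods: the twin model and the PBI test always work on per-individual
mean outcomes and test the genotype-exposure interaction there; the LMM
uses all repeated measures and tests the G:E term for average-channel
scenario families and the G:E:T term for rate-of-change families. Power
(or type-I error, under null scenarios) is the proportion of p-values
below alpha across replicates, with binomial Monte-Carlo standard errors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import lmm as lmm_mod
from . import pbi as pbi_mod
from . import twin_model as twin_mod
from .cohort_sim import ScenarioConfig, simulate_cohort_data
from .prep import bonferroni_threshold, mean_over_time, quartile_categorize

__all__ = ["run_replicate", "estimate_power", "gxe_scan"]

_SEED_MOD = 2**31 - 1


def run_replicate(
    scenario: ScenarioConfig,
    methods=("twin", "lmm", "pbi"),
    seed=None,
    genetic_coding: str = "additive",
    n_permutations: int = 10000,
) -> dict:
    """Simulate one cohort and return the interaction p-value per method.

    A method that fails to converge yields NaN for that replicate (the
    replicate itself is retained). The LMM's tested term follows the
    scenario's ``analysis_target`` (G:E or G:E:T).
    """
    rng = np.random.default_rng(seed)
    cohort, geno, env, records = simulate_cohort_data(scenario, seed=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summaries = mean_over_time(records)
    out = {}
    if "twin" in methods:
        fit = twin_mod.fit_twin_model(summaries, genetic_coding=genetic_coding)
        out["twin"] = twin_mod.test_effect(fit, "G:E").p_value
    if "lmm" in methods:
        fit = lmm_mod.fit_lmm(
            records,
            genetic_coding=genetic_coding,
            test_target=scenario.analysis_target,
        )
        term = "G:E" if scenario.analysis_target == "GE" else "G:E:T"
        out["lmm"] = lmm_mod.test_effect(fit, term).p_value
    if "pbi" in methods:
        res = pbi_mod.family_permutation_pvalue(
            summaries["mean_bmi"].to_numpy(),
            summaries["genotype"].to_numpy(),
            summaries["exposure"].to_numpy(),
            summaries["family_id"].to_numpy(),
            B=n_permutations,
            seed=rng,
        )
        out["pbi"] = res.p_perm
    return out


def estimate_power(
    scenarios,
    methods=("twin", "lmm", "pbi"),
    n_replicates: int = 500,
    alpha: float = 0.05,
    base_seed: int = 0,
    genetic_coding: str = "additive",
    n_permutations: int = 1000,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Rejection proportions per scenario x method over seeded replicates.

    ``scenarios`` is a ScenarioConfig or an iterable of them. Replicate r
    of every scenario uses seed (base_seed + r) mod 2^31-1, so the table
    is reproducible from (scenarios, n_replicates, base_seed) alone and is
    independent of scheduling or worker count.
    """
    if isinstance(scenarios, ScenarioConfig):
        scenarios = [scenarios]
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [(base_seed + r) % _SEED_MOD for r in range(n_replicates)]

    rows = []
    for sc in scenarios:
        if n_jobs != 1:
            from joblib import Parallel, delayed

            pvals = Parallel(n_jobs=n_jobs)(
                delayed(run_replicate)(
                    sc, methods, s, genetic_coding, n_permutations
                )
                for s in seeds
            )
        else:
            pvals = [
                run_replicate(sc, methods, s, genetic_coding, n_permutations)
                for s in seeds
            ]
        for m in methods:
            p = np.array([d[m] for d in pvals], dtype=float)
            ok = np.isfinite(p)
            n_ok = int(ok.sum())
            prop = float((p[ok] < alpha).mean()) if n_ok else np.nan
            rows.append(
                {
                    "scenario": sc.name,
                    "effect_channel": sc.effect_channel,
                    "beta_GE": sc.beta_GE,
                    "beta_GTE": sc.beta_GTE,
                    "beta_G": sc.beta_G,
                    "beta_GT": sc.beta_GT,
                    "beta_E": sc.beta_E,
                    "method": m,
                    "coding": genetic_coding,
                    "alpha": alpha,
                    "n_replicates": n_replicates,
                    "n_missing": n_replicates - n_ok,
                    "rejection_proportion": prop,
                    "mc_se": (
                        float(np.sqrt(prop * (1 - prop) / n_ok)) if n_ok else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def gxe_scan(
    records: pd.DataFrame,
    genotypes: pd.DataFrame,
    exposures: pd.DataFrame,
    methods=("twin", "lmm", "pbi"),
    alpha: float = 0.05,
    n_tests: int = 9,
    genetic_coding: str = "additive",
    n_permutations: int = 10000,
    seed=None,
    min_visits: int = 2,
) -> pd.DataFrame:
    """Scan variant x exposure pairs for GE interaction with each method.

    ``records`` are long-format phenotype rows (without genotype/exposure
    columns, or they are ignored); ``genotypes`` is an individual-indexed
    frame of QC-passed variants; ``exposures`` an individual-indexed frame
    of exposure variables (binary/categorical used as-is; continuous
    exposures are quartile-categorized for the PBI test). Flags are
    reported at the raw alpha and at the Bonferroni level alpha/n_tests
    (tests within one exposure).
    """
    thr = bonferroni_threshold(alpha, n_tests)
    rng = np.random.default_rng(seed)
    base = records.drop(columns=["genotype", "exposure"], errors="ignore")
    rows = []
    for exp_name in exposures.columns:
        evals = exposures[exp_name]
        is_binaryish = evals.dropna().nunique() <= 4
        pbi_e = evals if is_binaryish else pd.Series(
            quartile_categorize(evals.to_numpy(dtype=float)), index=evals.index
        )
        for var in genotypes.columns:
            g = genotypes[var]
            rec = base.copy()
            rec["genotype"] = rec["individual_id"].map(g)
            rec["exposure"] = rec["individual_id"].map(evals)
            rec = rec.dropna(subset=["genotype", "exposure"])
            if rec.empty or rec["genotype"].nunique() < 2:
                rows.append(
                    {"variant": var, "exposure": exp_name, "method": "all",
                     "effect": None, "p_raw": np.nan, "skipped": True,
                     "significant_raw": False, "significant_bonferroni": False}
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summ = mean_over_time(rec, min_visits=min_visits)
            for m in methods:
                if m == "twin":
                    fit = twin_mod.fit_twin_model(summ, genetic_coding=genetic_coding)
                    p = twin_mod.test_effect(fit, "G:E").p_value
                    eff = "G:E"
                elif m == "lmm":
                    fit = lmm_mod.fit_lmm(
                        rec, genetic_coding=genetic_coding, test_target="GE"
                    )
                    p = lmm_mod.test_effect(fit, "G:E").p_value
                    eff = "G:E"
                elif m == "pbi":
                    e_for_pbi = summ["individual_id"].map(pbi_e).to_numpy()
                    res = pbi_mod.family_permutation_pvalue(
                        summ["mean_bmi"].to_numpy(),
                        summ["genotype"].to_numpy(),
                        e_for_pbi,
                        summ["family_id"].to_numpy(),
                        B=n_permutations,
                        seed=rng,
                    )
                    p = res.p_perm
                    eff = "I_T"
                else:
                    raise ValueError(f"unknown method {m!r}")
                rows.append(
                    {
                        "variant": var,
                        "exposure": exp_name,
                        "method": m,
                        "effect": eff,
                        "p_raw": p,
                        "skipped": False,
                        "significant_raw": bool(np.isfinite(p) and p < alpha),
                        "significant_bonferroni": bool(np.isfinite(p) and p < thr),
                    }
                )
    return pd.DataFrame(rows)
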
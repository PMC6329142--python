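"""Shared data-preparation operators.

Time-averaging of repeated outcomes, genotype codings, exposure
summarization (carry-forward follow-up proportions), quartile
categorization for partition-based testing, variant QC (MAF, missingness,
Hardy-Weinberg), and Bonferroni adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_over_time",
    "codominant_coding",
    "quartile_categorize",
    "followup_proportion",
    "variant_qc",
    "bonferroni_threshold",
]


def mean_over_time(records: pd.DataFrame, min_visits: int = 2) -> pd.DataFrame:
    """Summarize long-format records to one row per individual.

    The outcome and age are averaged (unweighted) over the individual's
    non-missing visits. Individuals with fewer than ``min_visits`` usable
    visits are dropped with a warning; the default of 2 corresponds to
    excluding anyone missing more than 4 of 6 scheduled measurements.

    Returns columns: individual_id, family_id, zygosity, sex, genotype,
    exposure, mean_bmi, mean_age, n_visits.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    rec = records.dropna(subset=["bmi"])
    grouped = rec.groupby("individual_id", sort=True)
    out = grouped.agg(
        family_id=("family_id", "first"),
        zygosity=("zygosity", "first"),
        sex=("sex", "first"),
        genotype=("genotype", "first"),
        exposure=("exposure", "first"),
        mean_bmi=("bmi", "mean"),
        mean_age=("age_months", "mean"),
        n_visits=("bmi", "size"),
    ).reset_index()
    short = out["n_visits"] < min_visits
    if short.any():
        warnings.warn(
            f"dropping {int(short.sum())} individual(s) with fewer than "
            f"{min_visits} usable visits",
            stacklevel=2,
        )
        out = out[~short].reset_index(drop=True)
    return out


def codominant_coding(g):
    """Recode additive genotypes into (het, hom_minor) indicators.

    Common-allele homozygotes (g=0) are the reference: 0 -> (0,0),
    1 -> (1,0), 2 -> (0,1). Missing values propagate as NaN.
    """
    g = np.asarray(g, dtype=float)
    ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = np.unique(g[~ok])
        raise ValueError(f"genotypes must be 0/1/2 or missing; found {bad}")
    het = np.where(np.isnan(g), np.nan, (g == 1).astype(float))
    hom = np.where(np.isnan(g), np.nan, (g == 2).astype(float))
    return het, hom


def quartile_categorize(x) -> np.ndarray:
    """Assign 4-level ordinal categories (1-4) by sample quartiles.

    Values exactly on a quartile boundary go to the lower category; missing
    values propagate. Requires at least 4 distinct finite values.
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 4:
        raise ValueError(
            "need >= 4 distinct finite values for quartile categories; "
            "use fewer levels for coarser data"
        )
    qs = np.quantile(finite, [0.25, 0.5, 0.75])
    cat = np.full(x.shape, np.nan)
    m = np.isfinite(x)
    # category = 1 + number of quartile boundaries strictly below x
    cat[m] = np.searchsorted(qs, x[m], side="left") + 1
    return cat


def followup_proportion(status, ages) -> float:
    """Proportion of follow-up time spent in status 1, with carry-forward.

    A status reported at a visit is assumed to hold for the whole interval
    until the next visit. Intervals whose length cannot be computed (either
    endpoint age missing) or whose starting status is missing are excluded
    from both numerator and denominator. Returns NaN with a warning when no
    interval is usable.
    """
    status = np.asarray(status, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if status.shape != ages.shape or status.ndim != 1:
        raise ValueError("status and ages must be 1-D of equal length")
    if len(ages) < 2:
        raise ValueError("need >= 2 visits to form a follow-up interval")
    lengths = ages[1:] - ages[:-1]
    usable = np.isfinite(lengths) & np.isfinite(status[:-1])
    if np.any(lengths[np.isfinite(lengths)] <= 0):
        raise ValueError("ages must be increasing where observed")
    if not usable.any():
        warnings.warn("no usable follow-up interval; returning NaN", stacklevel=2)
        return float("nan")
    total = lengths[usable].sum()
    exposed = (lengths[usable] * status[:-1][usable]).sum()
    return float(exposed / total)


def _hwe_chisq(n0: int, n1: int, n2: int):
    """1-df chi-square goodness-of-fit against Hardy-Weinberg proportions.

    Genotype counts are (common hom, het, minor hom). Monomorphic samples
    fit HW exactly by convention (statistic 0, p 1).
    """
    n = n0 + n1 + n2
    if n == 0:
        return 0.0, 1.0
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def variant_qc(
    genotypes: pd.DataFrame,
    family_ids=None,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    hwe_alpha: float = 0.01,
) -> tuple[list, pd.DataFrame]:
    """Filter variants on MAF, missingness and Hardy-Weinberg equilibrium.

    ``genotypes`` is an individuals x variants frame of {0, 1, 2, NaN}.
    MAF and missingness use all individuals; the HWE chi-square test is run
    on one individual per family (lowest index id) when ``family_ids`` is
    given, so duplicated MZ genotypes and sib sharing do not distort the
    genotype counts. Variants failing any filter are dropped. Returns
    (kept variant names, report frame with columns variant, maf,
    missingness, hwe_p, kept). An empty kept list is a valid outcome.
    """
    report = []
    if family_ids is not None:
        fam = pd.Series(np.asarray(family_ids), index=genotypes.index)
        founder_idx = (
            pd.Series(genotypes.index, index=genotypes.index)
            .groupby(fam)
            .min()
            .to_numpy()
        )
    else:
        founder_idx = genotypes.index.to_numpy()

    for var in genotypes.columns:
        g = genotypes[var].to_numpy(dtype=float)
        missing = np.isnan(g)
        miss_frac = missing.mean() if len(g) else 0.0
        obs = g[~missing]
        if obs.size:
            p = obs.sum() / (2 * obs.size)
            maf = min(p, 1 - p)
        else:
            maf = 0.0
        gf = genotypes.loc[founder_idx, var].to_numpy(dtype=float)
        gf = gf[~np.isnan(gf)]
        # Orient counts so index 2 is the minor homozygote.
        if gf.size and gf.sum() / (2 * gf.size) > 0.5:
            gf = 2 - gf
        _, hwe_p = _hwe_chisq(
            int((gf == 0).sum()), int((gf == 1).sum()), int((gf == 2).sum())
        )
        kept = (maf >= maf_min) and (miss_frac <= max_missing) and (hwe_p >= hwe_alpha)
        report.append(
            {"variant": var, "maf": maf, "missingness": miss_frac,
             "hwe_p": hwe_p, "kept": kept}
        )
    report = pd.DataFrame(report)
    kept_vars = report.loc[report["kept"], "variant"].tolist()
    return kept_vars, report


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Adjusted per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
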
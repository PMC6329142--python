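"""Wald and likelihood-ratio testing shared by the twin model and the LMM.

Single-coefficient effects are tested with a Wald z statistic against the
standard normal (large-sample ML convention); effects spanning several
design columns (e.g. a co-dominant interaction) use a likelihood-ratio
test against a refitted null, with a chi-square reference on the number
of dropped columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["EffectTest", "wald_test", "lr_test", "test_effect"]


@dataclass(frozen=True)
class EffectTest:
    term: str
    statistic: float
    df: int
    p_value: float
    kind: str  # "wald" or "lrt"


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z test of a single coefficient. Returns (z, p)."""
    if se <= 0 or not math.isfinite(se):
        return float("nan"), float("nan")
    z = estimate / se
    return z, float(2.0 * special.ndtr(-abs(z)))

def lr_test(loglik_full: float, loglik_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square test. Returns (statistic, p)."""
    stat = max(2.0 * (loglik_full - loglik_null), 0.0)
    return stat, float(stats.chi2.sf(stat, df=df))


def test_effect(fit, term) -> EffectTest:
    """Test a named effect (or term group) in a fitted model.

    ``term`` may be a design-column name, a term-group name registered in
    ``fit.term_groups`` (e.g. "G:E" expanding to the co-dominant indicator
    interactions), or an explicit sequence of column names. One column ->
    Wald; several -> LRT with the null model refitted without them.
    """
    if isinstance(term, str):
        label = term
        cols = fit.term_groups.get(term, [term])
    else:
        cols = list(term)
        label = "+".join(cols)
    fe = fit.fixed_effects.set_index("term")
    missing = [c for c in cols if c not in fe.index]
    if missing:
        raise KeyError(f"term(s) {missing} not in the fitted design")
    if not getattr(fit, "converged", True):
        return EffectTest(label, float("nan"), len(cols), float("nan"), "wald")
    if len(cols) == 1:
        est = float(fe.loc[cols[0], "estimate"])
        se = float(fe.loc[cols[0], "se"])
        z, p = wald_test(est, se)
        return EffectTest(label, z, 1, p, "wald")
    null_fit = fit.refit_without(cols)
    if not getattr(null_fit, "converged", True):
        return EffectTest(label, float("nan"), len(cols), float("nan"), "lrt")
    stat, p = lr_test(fit.loglik, null_fit.loglik, df=len(cols))
    return EffectTest(label, stat, len(cols), p, "lrt")


def design_matrix(
    summary_like,
    genetic_coding: str,
    extra: dict | None = None,
    interaction_with: str = "E",
    drop_terms=(),
):
    """Assemble fixed-effect columns shared by the twin model and the LMM.

    Returns (X, column names, term_groups). ``summary_like`` must provide
    sex ("F"/"M"), genotype, exposure arrays plus any entries of ``extra``
    (e.g. age columns). The genotype enters additively (one column "G") or
    co-dominantly (indicator columns "het"/"hom").
    """
    from .prep import codominant_coding

    sex = (np.asarray(summary_like["sex"]) == "M").astype(float)
    g = np.asarray(summary_like["genotype"], dtype=float)
    e = np.asarray(summary_like["exposure"], dtype=float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones_like(sex), "sex": sex}
    if extra:
        cols.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    groups: dict[str, list[str]] = {}
    if genetic_coding == "additive":
        cols["G"] = g
        groups["G"] = ["G"]
        g_cols = {"G": g}
    elif genetic_coding == "codominant":
        het, hom = codominant_coding(g)
        cols["het"] = het
        cols["hom"] = hom
        groups["G"] = ["het", "hom"]
        g_cols = {"het": het, "hom": hom}
    else:
        raise ValueError("genetic_coding must be 'additive' or 'codominant'")
    cols["E"] = e
    groups["E"] = ["E"]

    def add_products(base_cols: dict, factor: np.ndarray, suffix: str, gname: str):
        names = []
        for cname, cvals in base_cols.items():
            name = f"{cname}:{suffix}"
            cols[name] = cvals * factor
            names.append(name)
        groups[gname] = names

    if interaction_with == "E":
        add_products(g_cols, e, "E", "G:E")
    elif interaction_with == "E+T":
        t = np.asarray(extra["T"], dtype=float)
        add_products(g_cols, t, "T", "G:T")
        cols["E:T"] = e * t
        groups["E:T"] = ["E:T"]
        add_products(g_cols, e, "E", "G:E")
        add_products({k: cols[k] for k in groups["G:E"]}, t, "T", "G:E:T")
        # rename e.g. "G:E:T" columns: products were built from "G:E" names
    else:
        raise ValueError("interaction_with must be 'E' or 'E+T'")

    if drop_terms:
        drop = set(drop_terms)
        cols = {k: v for k, v in cols.items() if k not in drop}
        groups = {
            k: [c for c in v if c not in drop] for k, v in groups.items()
        }
        groups = {k: v for k, v in groups.items() if v}
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names, groups
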
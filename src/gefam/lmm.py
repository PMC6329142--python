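"""Kinship-covariance linear mixed model on repeated measures.

Every individual gets one random intercept; the covariance of the random
intercepts across individuals is sigma2_g times the relationship matrix
(2 x kinship: self 1, MZ co-twin 1, DZ co-twin 0.5), inducing both the
longitudinal correlation within an individual and the familial correlation
within a pair. The marginal covariance of the stacked outcomes is

    Var(Y) = sigma2_g * Z K Z' + sigma2_res * I

with Z the individual-incidence matrix. The fixed-effect trend is
segmented in age with a hinge at 6 months (fast infant growth, then
plateau), plus sex, genotype, exposure and the tested interaction
products. Fitting is ML (so fixed-effect LRTs are valid), with fixed
effects profiled by GLS and the two variance components optimized on the
log scale; family blocks are handled by per-pattern eigendecomposition,
so MZ blocks being singular is harmless (the marginal covariance adds
sigma2_res * I and stays positive definite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._inference import EffectTest, design_matrix, test_effect as _test_effect

__all__ = ["KinshipMatrix", "LMMFit", "build_kinship", "fit_lmm", "test_effect"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class KinshipMatrix:
    """Relationship matrix (2 x kinship) over individuals, block-diagonal
    by twin pair: diagonal 1, MZ off-diagonal 1, DZ off-diagonal 0.5."""

    ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match ids")

    def coeff(self, id1, id2) -> float:
        i = int(np.flatnonzero(self.ids == id1)[0])
        j = int(np.flatnonzero(self.ids == id2)[0])
        return float(self.matrix[i, j])

    def to_sparse_frame(self) -> pd.DataFrame:
        """Nonzero entries as a 3-column (id1, id2, coefficient) table."""
        i, j = np.nonzero(np.triu(self.matrix))
        return pd.DataFrame(
            {"id1": self.ids[i], "id2": self.ids[j],
             "coefficient": self.matrix[i, j]}
        )


def build_kinship(cohort) -> KinshipMatrix:
    """Relationship matrix for a twin cohort: one 2x2 block per pair."""
    n = cohort.n_families
    ids = cohort.individual_ids.ravel()
    m = np.zeros((2 * n, 2 * n))
    np.fill_diagonal(m, 1.0)
    off = np.where(cohort.zygosity == "MZ", 1.0, 0.5)
    for f in range(n):
        m[2 * f, 2 * f + 1] = m[2 * f + 1, 2 * f] = off[f]
    return KinshipMatrix(ids=ids, matrix=m)


@dataclass
class LMMFit:
    """Fitted kinship LMM: fixed effects, variance components, likelihood."""

    fixed_effects: pd.DataFrame
    sigma2_g: float
    sigma2_res: float
    loglik: float
    converged: bool
    formula: str
    reml: bool = False
    term_groups: dict = field(default_factory=dict)
    _refit: callable = None

    def refit_without(self, terms) -> "LMMFit":
        if self._refit is None:
            raise RuntimeError("fit does not support refitting")
        return self._refit(terms)

    def summary_frame(self) -> pd.DataFrame:
        fe = self.fixed_effects.copy()
        vc = pd.DataFrame(
            {
                "term": ["sigma2_g", "sigma2_res", "loglik"],
                "estimate": [self.sigma2_g, self.sigma2_res, self.loglik],
                "se": np.nan,
            }
        )
        return pd.concat([fe, vc], ignore_index=True)


class _BlockData:
    """Per-family blocks rotated into the eigenbasis of the random-effect
    covariance pattern, reduced to per-eigenvalue cross-products.

    For a family block, Var(Y) = sigma2_g * B + sigma2_res * I where
    B = Q diag(lam) Q'. In the rotated coordinates the covariance is
    diagonal with weights sigma2_g*lam + sigma2_res, so the GLS normal
    equations and the log-likelihood are linear in the per-eigenvalue
    cross-products, which are accumulated once. Each likelihood evaluation
    is then O(n_eigenvalues * p^2) regardless of cohort size.
    """

    def __init__(self, X, y, family, individual, pair_coeff):
        family = np.asarray(family)
        individual = np.asarray(individual)
        order = np.lexsort((individual, family))
        X, y = X[order], y[order]
        family, individual = family[order], individual[order]
        fams, starts = np.unique(family, return_index=True)
        bounds = np.append(starts, len(family))
        self.p = X.shape[1]
        self.n_obs = len(y)

        # Group families by covariance pattern (pair coefficient + member
        # visit counts); eigendecompose B once per pattern.
        buckets: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
        for fi, fam in enumerate(fams):
            lo, hi = bounds[fi], bounds[fi + 1]
            inds, counts = np.unique(individual[lo:hi], return_counts=True)
            if len(inds) > 2:
                raise ValueError("families with more than two members unsupported")
            k = pair_coeff(fam) if len(inds) == 2 else 0.0
            key = (float(k), tuple(int(c) for c in counts))
            buckets.setdefault(key, []).append((X[lo:hi], y[lo:hi]))

        self.patterns = []
        for (k, counts), members in buckets.items():
            nb = sum(counts)
            B = np.zeros((nb, nb))
            pos = np.cumsum((0,) + counts)
            for a in range(len(counts)):
                B[pos[a]:pos[a + 1], pos[a]:pos[a + 1]] = 1.0
            if len(counts) == 2:
                B[pos[0]:pos[1], pos[1]:pos[2]] = k
                B[pos[1]:pos[2], pos[0]:pos[1]] = k
            lam, Q = np.linalg.eigh(B)
            Xs = np.stack([m[0] for m in members])  # (nf, nb, p)
            ys = np.stack([m[1] for m in members])  # (nf, nb)
            Xr = np.einsum("ij,nik->njk", Q, Xs, optimize=True)
            yr = np.einsum("ij,ni->nj", Q, ys, optimize=True)
            # Per-eigenvalue cross-products summed over families.
            M = np.einsum("nkp,nkq->kpq", Xr, Xr, optimize=True)
            u = np.einsum("nkp,nk->kp", Xr, yr, optimize=True)
            q = np.einsum("nk,nk->k", yr, yr)
            self.patterns.append(
                {"lam": lam, "n_fam": len(members), "M": M, "u": u, "q": q}
            )
        self.y_var = float(np.var(y, ddof=1)) if len(y) > 1 else 1.0

    def profile(self, s2g: float, s2r: float, reml: bool = False):
        """GLS fixed effects and profile log-likelihood at the variances."""
        if s2r <= 0 or s2g < 0 or not np.isfinite(s2g + s2r):
            return -np.inf, None, None
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        quad_y = 0.0
        logdet = 0.0
        for pat in self.patterns:
            w = s2g * pat["lam"] + s2r
            d = 1.0 / w
            A += np.einsum("k,kpq->pq", d, pat["M"])
            b += d @ pat["u"]
            quad_y += float(d @ pat["q"])
            logdet += pat["n_fam"] * float(np.log(w).sum())
        try:
            beta = np.linalg.solve(A, b)
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        ll = -0.5 * (self.n_obs * _LOG2PI + logdet + quad_y - b @ beta)
        if reml:
            sign, ld = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf, None, None
            ll += 0.5 * self.p * _LOG2PI - 0.5 * ld
        return ll, beta, cov


def _pair_coeff_lookup(records: pd.DataFrame, kinship: KinshipMatrix | None):
    if kinship is None:
        zmap = records.groupby("family_id")["zygosity"].first()
        return lambda fam: 1.0 if zmap[fam] == "MZ" else 0.5
    members = records.groupby("family_id")["individual_id"].unique()

    def coeff(fam):
        ids = members[fam]
        return kinship.coeff(ids[0], ids[1])

    return coeff


def fit_lmm(
    records: pd.DataFrame,
    kinship: KinshipMatrix | None = None,
    genetic_coding: str = "additive",
    test_target: str = "GE",
    knot_months: float = 6.0,
    reml: bool = False,
    drop_terms=(),
    fix_sigma2_g: float | None = None,
    time_basis: str = "hinge",
) -> LMMFit:
    """Fit the kinship-covariance LMM to long-format records by ML.

    Fixed effects: intercept, sex, age T, the hinge max(0, T - knot),
    genotype, exposure, and for ``test_target="GE"`` the genotype-exposure
    product; ``test_target="GTE"`` additionally includes G:T, E:T, G:E and
    the tested three-way G:E:T product (full hierarchy below the tested
    term). When ``kinship`` is omitted the pair coefficients are derived
    from the zygosity column (MZ 1, DZ 0.5).

    ``time_basis`` selects the segmented-trend basis: "hinge" (default)
    uses max(0, T - knot) in age; "visit_rule" instead zeroes the extra
    slope at the first two visits and uses T - knot afterwards, matching
    the trajectory generator's segmentation exactly (useful for parameter
    recovery checks; requires a ``visit`` column).
    """
    if test_target not in ("GE", "GTE"):
        raise ValueError("test_target must be 'GE' or 'GTE'")
    T = records["age_months"].to_numpy(dtype=float)
    if time_basis == "hinge":
        hinge = np.maximum(0.0, T - knot_months)
    elif time_basis == "visit_rule":
        visit = records["visit"].to_numpy()
        hinge = np.where(visit <= 2, 0.0, T - knot_months)
    else:
        raise ValueError("time_basis must be 'hinge' or 'visit_rule'")
    extra = {"T": T, "T_hinge": hinge}
    X, names, groups = design_matrix(
        records,
        genetic_coding,
        extra=extra,
        interaction_with="E" if test_target == "GE" else "E+T",
        drop_terms=drop_terms,
    )
    # Singular-design guard: name the offending column.
    if len(X):
        norms = np.linalg.norm(X - X.mean(axis=0), axis=0)
        const = [n for n, s in zip(names, norms) if n != "intercept" and s == 0]
        if const:
            raise ValueError(f"design column(s) {const} are constant (singular design)")
    y = records["bmi"].to_numpy(dtype=float)
    data = _BlockData(
        X, y, records["family_id"], records["individual_id"],
        _pair_coeff_lookup(records, kinship),
    )

    s2 = data.y_var

    if fix_sigma2_g is not None:

        def neg1(theta):
            ll, _, _ = data.profile(fix_sigma2_g, math.exp(theta[0]), reml)
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize_scalar(
            lambda t: neg1([t]), bounds=np.log([1e-8 * s2, 1e4 * s2]),
            method="bounded",
        )
        s2g, s2r = fix_sigma2_g, math.exp(res.x)
        converged = bool(res.success)
    else:

        def neg(theta):
            ll, _, _ = data.profile(math.exp(theta[0]), math.exp(theta[1]), reml)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        converged = False
        for f_g in (0.5, 0.1):
            x0 = np.log([max(f_g * s2, 1e-8), max((1 - f_g) * s2, 1e-8)])
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
            )
            tol = 1e-6 * (1.0 + abs(res.fun))
            if best is None or res.fun < best.fun - tol:
                best = res
                converged = bool(res.success)
            elif res.fun <= best.fun + tol:
                if res.fun < best.fun:
                    best = res
                converged = converged or bool(res.success)

        s2g, s2r = np.exp(best.x)
    ll, beta, cov = data.profile(s2g, s2r, reml)
    if beta is None:
        converged = False
        fe = pd.DataFrame({"term": names, "estimate": np.nan, "se": np.nan})
        ll = -np.inf
    else:
        fe = pd.DataFrame(
            {"term": names, "estimate": beta, "se": np.sqrt(np.diag(cov))}
        )

    def _refit(terms):
        return fit_lmm(
            records,
            kinship=kinship,
            genetic_coding=genetic_coding,
            test_target=test_target,
            knot_months=knot_months,
            reml=reml,
            drop_terms=tuple(drop_terms) + tuple(terms),
            fix_sigma2_g=fix_sigma2_g,
            time_basis=time_basis,
        )

    formula = (
        f"bmi ~ {' + '.join(names)} + (1 | individual, cov = sigma2_g * relationship)"
    )
    return LMMFit(
        fixed_effects=fe,
        sigma2_g=float(s2g),
        sigma2_res=float(s2r),
        loglik=float(ll),
        converged=converged,
        formula=formula,
        reml=reml,
        term_groups=groups,
        _refit=_refit,
    )


def test_effect(fit: LMMFit, term) -> EffectTest:
    """Wald (single column) or LRT (term group) test of a fitted effect."""
    return _test_effect(fit, term)
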
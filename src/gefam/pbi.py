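"""Partition-based score I (PBI) test with family-constrained permutation.

The PBI test is a nonparametric screen for interaction between two
categorical factors. For a partition of the sample into cells i = 1..k,
the dispersion statistic

    I = sum_i (n_i / n) * (ybar_i - ybar)^2 / (s2_y / n_i)

measures how much outcome variation the partition explains (s2_y is the
overall sample variance, ybar the grand mean). The interaction statistic
contrasts the crossed partition against the best single-factor one:

    I_T = I_GE - max(I_G, I_E)

Significance comes from permutation constrained to within families:
outcomes are shuffled among the members of each family (a fair exchange
under exchangeable co-twins) while every individual keeps their (G, E)
pair, and the one-sided upper-tail p-value is (1 + exceedances) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PBIResult",
    "dispersion_statistic",
    "pbi_statistic",
    "family_permutation_pvalue",
]


@dataclass
class PBIResult:
    I_GE: float
    I_G: float
    I_E: float
    I_T: float
    p_perm: float | None = None
    B: int | None = None
    cell_table: pd.DataFrame | None = None
    variance_divisor: str = "n-1"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "I_GE": self.I_GE, "I_G": self.I_G, "I_E": self.I_E,
                    "I_T": self.I_T, "p_perm": self.p_perm, "B": self.B,
                    "variance_divisor": self.variance_divisor,
                }
            ]
        )


def _prep_outcome(y):
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y must be 1-D with n >= 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    s2 = float(np.var(y, ddof=1))
    return y, float(y.mean()), s2


def dispersion_statistic(y, labels) -> float:
    """Dispersion statistic I of a partition of ``y`` into label cells.

    Empty cells are skipped; a constant outcome (zero sample variance)
    yields I = 0 with a warning, since every cell mean equals the grand
    mean.
    """
    y, ybar, s2 = _prep_outcome(y)
    labels = np.asarray(labels)
    if labels.shape != y.shape:
        raise ValueError("labels must align with y")
    if s2 == 0.0:
        warnings.warn("constant outcome: dispersion statistic is 0", stacklevel=2)
        return 0.0
    n = len(y)
    _, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=y)
    means = sums / counts
    return float(np.sum((counts / n) * (means - ybar) ** 2 * counts / s2))


def _cells(g, e):
    g = np.asarray(g)
    e = np.asarray(e)
    gu, gi = np.unique(g, return_inverse=True)
    eu, ei = np.unique(e, return_inverse=True)
    cell = gi * len(eu) + ei
    return gi, ei, cell, gu, eu


def _stat_from_sums(sums, counts, n, ybar, s2):
    m = counts > 0
    means = sums[..., m] / counts[m]
    w = (counts[m] / n) * counts[m] / s2
    return ((means - ybar) ** 2 * w).sum(axis=-1)


def pbi_statistic(y, g_labels, e_labels) -> PBIResult:
    """Compute I_GE, I_G, I_E and I_T for the observed labeling.

    I_T may be negative (crossing can dilute cells); it is reported
    untruncated. The per-cell table lists cell label, size and mean.
    """
    y, ybar, s2 = _prep_outcome(y)
    gi, ei, cell, gu, eu = _cells(g_labels, e_labels)
    n = len(y)
    n_cells = len(gu) * len(eu)
    counts_ge = np.bincount(cell, minlength=n_cells).astype(float)
    sums_ge = np.bincount(cell, weights=y, minlength=n_cells)
    if s2 == 0.0:
        warnings.warn("constant outcome: all dispersion statistics are 0",
                      stacklevel=2)
        I_ge = I_g = I_e = 0.0
    else:
        I_ge = float(_stat_from_sums(sums_ge, counts_ge, n, ybar, s2))
        cge = counts_ge.reshape(len(gu), len(eu))
        sge = sums_ge.reshape(len(gu), len(eu))
        I_g = float(_stat_from_sums(sge.sum(1), cge.sum(1), n, ybar, s2))
        I_e = float(_stat_from_sums(sge.sum(0), cge.sum(0), n, ybar, s2))
    table = pd.DataFrame(
        {
            "g": np.repeat(gu, len(eu)),
            "e": np.tile(eu, len(gu)),
            "n_i": counts_ge.astype(int),
            "mean_y": np.divide(
                sums_ge, counts_ge, out=np.full(n_cells, np.nan),
                where=counts_ge > 0,
            ),
        }
    )
    return PBIResult(
        I_GE=I_ge, I_G=I_g, I_E=I_e, I_T=I_ge - max(I_g, I_e), cell_table=table
    )


def family_permutation_pvalue(
    y, g_labels, e_labels, family_ids, B: int = 10000, seed=None,
    chunk: int = 2000,
) -> PBIResult:
    """PBI test with a within-family permutation p-value.

    Each of the B replicates independently permutes the outcome values
    among the members of every family (for twin pairs: a fair-coin swap),
    keeping each individual's (G, E) label pair intact, and recomputes
    I_T. The p-value is the one-sided upper-tail (1 + #{I_T_perm >=
    I_T_obs}) / (B + 1). Families of size 1 have nothing to exchange; if
    all families are singletons the test is vacuous and p = 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y, ybar, s2 = _prep_outcome(y)
    fam = np.asarray(family_ids)
    res = pbi_statistic(y, g_labels, e_labels)
    res.B = B

    fams, inv, counts = np.unique(fam, return_inverse=True, return_counts=True)
    if counts.max() == 1:
        warnings.warn(
            "all families have a single member: no within-family "
            "exchangeability, permutation p-value is 1",
            stacklevel=2,
        )
        res.p_perm = 1.0
        return res
    if counts.max() > 2:
        raise ValueError("families with more than two members are not supported")
    if s2 == 0.0:
        res.p_perm = 1.0
        return res

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(y)
    gi, ei, cell, gu, eu = _cells(g_labels, e_labels)
    n_cells = len(gu) * len(eu)
    onehot = np.zeros((n, n_cells))
    onehot[np.arange(n), cell] = 1.0
    counts_ge = onehot.sum(axis=0)
    cge = counts_ge.reshape(len(gu), len(eu))

    # Partner map: index of the co-twin (self for singletons).
    order = np.argsort(inv, kind="stable")
    partner = np.arange(n)
    pos = 0
    pair_members = []
    for c in counts:
        idx = order[pos:pos + c]
        if c == 2:
            partner[idx[0]], partner[idx[1]] = idx[1], idx[0]
            pair_members.append(idx)
        pos += c
    pair_members = np.array(pair_members)  # (n_pairs, 2)
    n_pairs = len(pair_members)

    obs = res.I_T
    exceed = 0
    arange = np.arange(n)
    for start in range(0, B, chunk):
        nb = min(chunk, B - start)
        swap = rng.random((nb, n_pairs)) < 0.5
        swap_ind = np.zeros((nb, n), dtype=bool)
        swap_ind[:, pair_members[:, 0]] = swap
        swap_ind[:, pair_members[:, 1]] = swap
        perm_idx = np.where(swap_ind, partner[None, :], arange[None, :])
        yp = y[perm_idx]  # (nb, n)
        sums_ge = yp @ onehot  # (nb, n_cells)
        I_ge = _stat_from_sums(sums_ge, counts_ge, n, ybar, s2)
        sge = sums_ge.reshape(nb, len(gu), len(eu))
        I_g = _stat_from_sums(sge.sum(2), cge.sum(1), n, ybar, s2)
        I_e = _stat_from_sums(sge.sum(1), cge.sum(0), n, ybar, s2)
        I_t = I_ge - np.maximum(I_g, I_e)
        exceed += int(np.sum(I_t >= obs - 1e-12))
    res.p_perm = (1.0 + exceed) / (B + 1.0)
    return res
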
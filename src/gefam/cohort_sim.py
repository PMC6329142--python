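"""Simulation of longitudinal twin cohorts with gene-environment interactions.

Generates the full data-generating chain for a twin-family BMI study:
family/zygosity/sex skeletons with visit schedules, biallelic SNP genotypes
under random mating and Mendelian transmission, independent binary
environmental exposures, and BMI trajectories from a linear mixed model
with ACE-structured random intercepts/slopes and a segmented time trend.

The generating model for individual j of pair i at visit k is

    Y_ijk = (b0 + C0_ij) + bS*S_ij + (bT + CT_ij)*T_ijk + bT'*T'_ijk
            + bG*G_ij + bGT*G_ij*T_ijk + bE*E_ij + theta_ijk + eps_ijk

where T'_ijk = 0 for the first two visits and T_ijk - 6 afterwards
(fast infant growth before ~6 months, plateau after), and theta carries
the gene-environment interaction: bGE*M[G,E] when the interaction acts on
the outcome average, bGTE*M[G,E]*T when it acts on the rate of change.
M is a 3x2 interaction matrix over genotype (0/1/2 minor alleles) and
exposure (0/1); named presets cover linear, XOR, conditional-dominant and
small-marginal-effect patterns.

Random intercepts (C0) and slopes (CT) are bivariate normal within a pair
with ACE covariance: variance sigma2_A + sigma2_C, covariance
sigma2_A + sigma2_C for MZ pairs and sigma2_A/2 + sigma2_C for DZ pairs
(analogously tau2 for slopes). Intercept and slope vectors are mutually
independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "CohortStructure",
    "Genotypes",
    "InteractionMatrix",
    "ScenarioConfig",
    "DEFAULT_VISIT_AGE_MEANS",
    "DEFAULT_VISIT_AGE_SDS",
    "DEFAULT_SEX_PAIR_PROBS",
    "generate_cohort",
    "simulate_genotypes",
    "simulate_environment",
    "interaction_preset",
    "scenario_preset",
    "simulate_trajectories",
    "simulate_cohort_data",
]

#: Visit-age schedule (months): birth plus five follow-ups. Means/SDs mirror
#: the observed follow-up ages of the twin cohort the simulator emulates.
DEFAULT_VISIT_AGE_MEANS = (0.0, 6.28, 19.49, 31.77, 49.85, 62.25)
DEFAULT_VISIT_AGE_SDS = (0.0, 0.74, 0.75, 0.96, 1.82, 3.23)

#: Sex-pair composition (FF/MM/FM). FM applies to DZ pairs only; MZ pairs
#: draw from FF/MM renormalized.
DEFAULT_SEX_PAIR_PROBS = {"FF": 0.42, "MM": 0.35, "FM": 0.23}

_N_VISITS = 6


@dataclass(frozen=True)
class CohortStructure:
    """Family skeleton: zygosity, sex and shared visit ages per twin pair.

    Attributes
    ----------
    zygosity : (n_families,) array of "MZ"/"DZ"
    sex : (n_families, 2) array of "F"/"M"; MZ pairs are same-sex.
    visit_ages : (n_families, n_visits) ages in months, shared by co-twins,
        strictly increasing, first visit at age 0 (birth).
    """

    zygosity: np.ndarray
    sex: np.ndarray
    visit_ages: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.zygosity)
        if not np.all(np.isin(z, ["MZ", "DZ"])):
            raise ValueError("zygosity entries must be 'MZ' or 'DZ'")
        mz = z == "MZ"
        if self.n_families and np.any(self.sex[mz, 0] != self.sex[mz, 1]):
            raise ValueError("MZ pairs must be same-sex")
        ages = self.visit_ages
        if self.n_families:
            if np.any(ages[:, 0] != 0.0):
                raise ValueError("age at the first visit (birth) must be 0")
            if np.any(np.diff(ages, axis=1) <= 0):
                raise ValueError("visit ages must be strictly increasing")

    @property
    def n_families(self) -> int:
        return len(self.zygosity)

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_families

    @property
    def family_ids(self) -> np.ndarray:
        return np.arange(self.n_families)

    @property
    def individual_ids(self) -> np.ndarray:
        """Individual ids laid out as (n_families, 2): 2*family + member."""
        fam = self.family_ids
        return np.stack([2 * fam, 2 * fam + 1], axis=1)

    def individuals_frame(self) -> pd.DataFrame:
        """One row per individual: family_id, individual_id, zygosity, sex."""
        n = self.n_families
        return pd.DataFrame(
            {
                "family_id": np.repeat(self.family_ids, 2),
                "individual_id": self.individual_ids.ravel(),
                "zygosity": np.repeat(self.zygosity, 2),
                "sex": self.sex.ravel(),
            }
        )


@dataclass(frozen=True)
class Genotypes:
    """Child genotypes plus the parental genotypes they were transmitted from.

    Parents are retained so Mendelian consistency of the transmission step
    can be audited: each child genotype must be reachable as one allele from
    each parent.
    """

    child: np.ndarray  #: (n_families, 2) minor-allele counts in {0,1,2}
    maternal: np.ndarray  #: (n_families,) parental minor-allele counts
    paternal: np.ndarray


@dataclass(frozen=True)
class InteractionMatrix:
    """3x2 multiplier table M[g, e] applied to the interaction effect size.

    Rows index the minor-allele count g in {0,1,2}, columns the exposure
    e in {0,1}. Entries are unitless multipliers of beta_GE (or beta_GTE);
    presets are normalized so that max |M| <= 2.
    """

    m: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 2):
            raise ValueError(f"interaction matrix must be 3x2, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("interaction matrix entries must be finite")
        object.__setattr__(self, "m", m)

    def __getitem__(self, key):
        return self.m[key]


_PRESET_MATRICES = {
    # rows g = 0, 1, 2; columns e = 0, 1
    "linear": [[0, 0], [0, 1], [0, 2]],
    "xor": [[0, 0], [1.5, 0], [0, 2]],
    "conditional_dominant": [[0, 0], [1, 2], [2, 2]],
    "small_marginal": [[0, 0], [0, 0], [0, 1]],
}


def interaction_preset(name: str) -> InteractionMatrix:
    """Return a canonical interaction-pattern matrix by name.

    ``linear`` is the multiplicative G*E pattern. ``xor`` is an extremely
    non-linear pattern in which the genetic effect flips entirely with
    exposure — heterozygote advantage when unexposed, a recessive effect
    when exposed — built so that the exposure contrast delta(g) =
    M[g,1] - M[g,0] is orthogonal to the additive genotype coding under
    Hardy-Weinberg weights at MAF 0.3: a multiplicative G x E regression
    term carries no signal from it, only a partition over the crossed
    cells does. In ``conditional_dominant`` the genetic effect is additive
    unexposed and plateaus (dominant) when exposed; ``small_marginal`` is
    a recessive effect triggered only under exposure.
    """
    try:
        m = _PRESET_MATRICES[name]
    except KeyError:
        raise ValueError(
            f"unknown interaction preset {name!r}; "
            f"available: {sorted(_PRESET_MATRICES)}"
        ) from None
    return InteractionMatrix(np.array(m, dtype=float), name=name)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one simulation scenario.

    All beta are fixed effects on BMI (kg/m^2; per-month where time enters),
    sigma2/tau2 the ACE variance components of the random intercept/slope,
    and sigma2_E the residual variance. ``effect_channel`` says whether the
    interaction acts on the outcome average ("average", via beta_GE), on the
    rate of change ("change", via beta_GTE), or not at all ("none").
    ``analysis_target`` records which interaction term the regression models
    should test for this scenario family (GE on averages vs GTE on slopes).
    """

    beta_0: float = 11.0
    beta_S: float = 0.5
    beta_T: float = 0.8
    beta_Tp: float = -0.8
    beta_G: float = 0.0
    beta_GT: float = 0.0
    beta_E: float = 0.0
    beta_GE: float = 0.0
    beta_GTE: float = 0.0
    sigma2_A: float = 3.0
    sigma2_C: float = 1.5
    tau2_A: float = 0.001
    tau2_C: float = 0.001
    sigma2_E: float = 1.5
    maf: float = 0.3
    exposure_freq: float = 0.3
    interaction: InteractionMatrix = field(
        default_factory=lambda: interaction_preset("linear")
    )
    effect_channel: str = "none"
    analysis_target: str = "GE"
    n_mz_pairs: int = 168
    n_dz_pairs: int = 226
    dropout_prob: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        for f in ("sigma2_A", "sigma2_C", "tau2_A", "tau2_C", "sigma2_E"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0, 0.5]")
        if not 0 <= self.exposure_freq <= 1:
            raise ValueError("exposure_freq must be in [0, 1]")
        if self.effect_channel not in ("none", "average", "change"):
            raise ValueError("effect_channel must be none/average/change")
        if self.analysis_target not in ("GE", "GTE"):
            raise ValueError("analysis_target must be GE or GTE")
        if self.effect_channel == "average" and (
            self.beta_GE == 0 or self.beta_GTE != 0
        ):
            raise ValueError("average channel requires beta_GE != 0, beta_GTE == 0")
        if self.effect_channel == "change" and (
            self.beta_GTE == 0 or self.beta_GE != 0
        ):
            raise ValueError("change channel requires beta_GTE != 0, beta_GE == 0")
        if self.effect_channel == "none" and (self.beta_GE or self.beta_GTE):
            raise ValueError("none channel requires beta_GE == beta_GTE == 0")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interaction"] = {
            "name": self.interaction.name,
            "m": self.interaction.m.tolist(),
        }
        return d


# Scenario grids: effect sizes the study design varies over.
_GE_GRID = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)
_GTE_GRID = np.array([0.001, 0.004, 0.007, 0.01, 0.015, 0.02, 0.025, 0.03])
_NULL_G_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
_NULL_GT_GRID = np.concatenate([[0.0], _GTE_GRID])


def _check_grid(value: float, grid: np.ndarray, label: str) -> float:
    hit = np.isclose(grid, value, atol=1e-9)
    if not hit.any():
        raise ValueError(
            f"{label}={value} not on the scenario grid {np.round(grid, 4).tolist()}"
        )
    return float(grid[hit][0])


def scenario_preset(
    family: str,
    *,
    beta_g: float | None = None,
    beta_gt: float | None = None,
    beta_ge: float | None = None,
    beta_gte: float | None = None,
    interaction: str | InteractionMatrix | None = None,
    **overrides,
) -> ScenarioConfig:
    """Build a scenario from the study's parameter grid.

    Families
    --------
    null_average : no interaction; genetic main effect ``beta_g`` on the
        grid 0..1 (step 0.1) with environment effect tied to 2*beta_g.
    null_change : no interaction; gene-time effect ``beta_gt`` on the GTE
        grid (plus 0) with environment effect tied to 40*beta_gt.
    ge_linear / ge_nonlinear : interaction on the average, ``beta_ge`` on
        0.1..1 (step 0.1); the linear family keeps beta_G=0.25, beta_E=0.5,
        the non-linear family zeroes the main effects and takes a named
        non-linear ``interaction`` pattern (default "xor").
    gte_linear / gte_nonlinear : interaction on the rate of change,
        ``beta_gte`` on 0.001..0.03; the linear family keeps beta_GT=0.01,
        beta_E=0.5.
    """
    if isinstance(interaction, str):
        interaction = interaction_preset(interaction)

    if family == "null_average":
        bg = 0.0 if beta_g is None else _check_grid(beta_g, _NULL_G_GRID, "beta_g")
        cfg = ScenarioConfig(
            beta_G=bg, beta_E=round(2 * bg, 10), effect_channel="none",
            analysis_target="GE", name=f"null_average(beta_g={bg})",
        )
    elif family == "null_change":
        bgt = 0.0 if beta_gt is None else _check_grid(beta_gt, _NULL_GT_GRID, "beta_gt")
        cfg = ScenarioConfig(
            beta_GT=bgt, beta_E=round(40 * bgt, 10), effect_channel="none",
            analysis_target="GTE", name=f"null_change(beta_gt={bgt})",
        )
    elif family in ("ge_linear", "ge_nonlinear"):
        if beta_ge is None:
            raise ValueError(f"{family} requires beta_ge")
        bge = _check_grid(beta_ge, _GE_GRID, "beta_ge")
        if family == "ge_linear":
            mat = interaction or interaction_preset("linear")
            cfg = ScenarioConfig(
                beta_G=0.25, beta_E=0.5, beta_GE=bge, interaction=mat,
                effect_channel="average", analysis_target="GE",
                name=f"ge_linear(beta_ge={bge})",
            )
        else:
            mat = interaction or interaction_preset("xor")
            cfg = ScenarioConfig(
                beta_GE=bge, interaction=mat, effect_channel="average",
                analysis_target="GE",
                name=f"ge_nonlinear[{mat.name}](beta_ge={bge})",
            )
    elif family in ("gte_linear", "gte_nonlinear"):
        if beta_gte is None:
            raise ValueError(f"{family} requires beta_gte")
        bgte = _check_grid(beta_gte, _GTE_GRID, "beta_gte")
        if family == "gte_linear":
            mat = interaction or interaction_preset("linear")
            cfg = ScenarioConfig(
                beta_GT=0.01, beta_E=0.5, beta_GTE=bgte, interaction=mat,
                effect_channel="change", analysis_target="GTE",
                name=f"gte_linear(beta_gte={bgte})",
            )
        else:
            mat = interaction or interaction_preset("xor")
            cfg = ScenarioConfig(
                beta_GTE=bgte, interaction=mat, effect_channel="change",
                analysis_target="GTE",
                name=f"gte_nonlinear[{mat.name}](beta_gte={bgte})",
            )
    else:
        raise ValueError(
            f"unknown scenario family {family!r}; available: null_average, "
            "null_change, ge_linear, ge_nonlinear, gte_linear, gte_nonlinear"
        )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_cohort(
    n_mz_pairs: int,
    n_dz_pairs: int,
    visit_age_means=DEFAULT_VISIT_AGE_MEANS,
    visit_age_sds=DEFAULT_VISIT_AGE_SDS,
    sex_pair_probs=None,
    seed=None,
) -> CohortStructure:
    """Generate a twin cohort skeleton: zygosity, sex-pairs and visit ages.

    Ages at visits beyond birth are drawn per family from
    Normal(mean_k, sd_k) truncated below at the previous visit's age, so
    schedules are strictly increasing; co-twins share the family schedule.
    The FM (opposite-sex) pair probability applies to DZ pairs only.
    """
    if n_mz_pairs < 0 or n_dz_pairs < 0:
        raise ValueError("pair counts must be >= 0")
    means = np.asarray(visit_age_means, dtype=float)
    sds = np.asarray(visit_age_sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1:
        raise ValueError("visit age means/sds must be 1-D and equal length")
    if np.any(np.diff(means) <= 0):
        raise ValueError("visit age means must be strictly increasing")
    if means[0] != 0:
        raise ValueError("first visit is birth: mean age must be 0")
    if np.any(sds < 0) or sds[0] != 0:
        raise ValueError("visit age sds must be >= 0 with sd 0 at birth")
    probs = dict(DEFAULT_SEX_PAIR_PROBS if sex_pair_probs is None else sex_pair_probs)

    rng = _as_rng(seed)
    n_fam = n_mz_pairs + n_dz_pairs
    zyg = np.array(["MZ"] * n_mz_pairs + ["DZ"] * n_dz_pairs, dtype=object)

    # Sex pairs: MZ draw FF/MM (renormalized); DZ draw FF/MM/FM.
    p_ff, p_mm, p_fm = probs["FF"], probs["MM"], probs["FM"]
    sex = np.empty((n_fam, 2), dtype=object)
    same = p_ff + p_mm
    u = rng.random(n_fam)
    for i in range(n_fam):
        if zyg[i] == "MZ":
            s = "F" if u[i] < p_ff / same else "M"
            sex[i] = (s, s)
        else:
            if u[i] < p_ff:
                sex[i] = ("F", "F")
            elif u[i] < p_ff + p_mm:
                sex[i] = ("M", "M")
            else:
                sex[i] = ("F", "M")

    # Visit ages: sequential truncated-normal draws via inverse CDF so the
    # schedule is strictly increasing within each family.
    n_visits = len(means)
    ages = np.zeros((n_fam, n_visits))
    for k in range(1, n_visits):
        lo = ages[:, k - 1]
        if sds[k] == 0:
            if np.any(means[k] <= lo):
                raise ValueError("degenerate visit age not above previous visit")
            ages[:, k] = means[k]
            continue
        a = special.ndtr((lo - means[k]) / sds[k])  # CDF at the lower bound
        u = a + (1.0 - a) * rng.random(n_fam)
        ages[:, k] = means[k] + sds[k] * special.ndtri(np.clip(u, 1e-12, 1 - 1e-16))
    return CohortStructure(zygosity=zyg, sex=sex, visit_ages=ages)


def simulate_genotypes(cohort: CohortStructure, maf: float, seed=None) -> Genotypes:
    """Simulate one biallelic SNP per family under random mating.

    Each parent's genotype is the sum of two independent Bernoulli(maf)
    alleles; a parent with genotype g transmits the minor allele with
    probability g/2 (Mendelian segregation). DZ co-twins get independent
    transmissions; MZ co-twins share a single transmission.
    """
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    rng = _as_rng(seed)
    n = cohort.n_families
    maternal = rng.binomial(1, maf, (n, 2)).sum(axis=1)
    paternal = rng.binomial(1, maf, (n, 2)).sum(axis=1)
    # Transmission draws for both (potential) meioses per parent.
    mat_tx = rng.binomial(1, maternal[:, None] / 2.0, (n, 2))
    pat_tx = rng.binomial(1, paternal[:, None] / 2.0, (n, 2))
    child = mat_tx + pat_tx
    mz = cohort.zygosity == "MZ"
    child[mz, 1] = child[mz, 0]  # one shared transmission for MZ pairs
    return Genotypes(child=child, maternal=maternal, paternal=paternal)


def simulate_environment(
    cohort: CohortStructure, exposure_freq: float, seed=None
) -> np.ndarray:
    """I.i.d. Bernoulli exposure per individual, independent within pairs.

    Returns an (n_families, 2) 0/1 array.
    """
    if not 0 <= exposure_freq <= 1:
        raise ValueError("exposure_freq must be in [0, 1]")
    rng = _as_rng(seed)
    return rng.binomial(1, exposure_freq, (cohort.n_families, 2))


def _pair_bivariate(rng, n, var, cov):
    """Draw n pairs from a zero-mean bivariate normal with common variance."""
    if cov > var + 1e-12:
        raise ValueError("pair covariance exceeds variance: not PSD")
    if var <= 0:
        return np.zeros((n, 2))
    # Shared + unique decomposition keeps the draw exact even when cov == var
    # (MZ blocks are rank 1).
    shared = rng.normal(0.0, np.sqrt(max(cov, 0.0)), n)
    unique = rng.normal(0.0, np.sqrt(max(var - cov, 0.0)), (n, 2))
    return shared[:, None] + unique


def simulate_trajectories(
    cohort: CohortStructure,
    genotypes,
    environments: np.ndarray,
    scenario: ScenarioConfig,
    seed=None,
) -> pd.DataFrame:
    """Simulate longitudinal BMI records for a cohort under a scenario.

    Returns long-format records with one row per individual-visit:
    family_id, individual_id, zygosity, sex, visit, age_months, bmi,
    genotype, exposure. The ``visit`` column is 1-based; the segmented
    time term T' is 0 at visits 1-2 and age-6 afterwards.
    """
    rng = _as_rng(seed)
    n = cohort.n_families
    geno = genotypes.child if isinstance(genotypes, Genotypes) else np.asarray(genotypes)
    env = np.asarray(environments)
    if geno.shape != (n, 2) or env.shape != (n, 2):
        raise ValueError("genotypes/environments must align with the cohort (n, 2)")
    sc = scenario

    T = cohort.visit_ages  # (n, V), shared within pair
    n_visits = T.shape[1]
    Tp = np.where(np.arange(n_visits) < 2, 0.0, T - 6.0)  # visit-index rule

    v0 = sc.sigma2_A + sc.sigma2_C
    vT = sc.tau2_A + sc.tau2_C
    mz = cohort.zygosity == "MZ"
    c0 = np.empty((n, 2))
    cT = np.empty((n, 2))
    for is_mz in (True, False):
        sel = mz if is_mz else ~mz
        m = int(sel.sum())
        cov0 = v0 if is_mz else 0.5 * sc.sigma2_A + sc.sigma2_C
        covT = vT if is_mz else 0.5 * sc.tau2_A + sc.tau2_C
        c0[sel] = _pair_bivariate(rng, m, v0, cov0)
        cT[sel] = _pair_bivariate(rng, m, vT, covT)

    S = (cohort.sex == "M").astype(float)  # (n, 2), 0 female / 1 male
    M = sc.interaction.m
    mult = M[geno.astype(int), env.astype(int)]  # (n, 2)

    # Broadcast to (n, 2, V)
    T3 = T[:, None, :]
    Tp3 = Tp[:, None, :]
    mean = (
        sc.beta_0
        + c0[:, :, None]
        + sc.beta_S * S[:, :, None]
        + (sc.beta_T + cT[:, :, None]) * T3
        + sc.beta_Tp * Tp3
        + sc.beta_G * geno[:, :, None]
        + sc.beta_GT * geno[:, :, None] * T3
        + sc.beta_E * env[:, :, None]
    )
    if sc.effect_channel == "average":
        mean = mean + sc.beta_GE * mult[:, :, None]
    elif sc.effect_channel == "change":
        mean = mean + sc.beta_GTE * mult[:, :, None] * T3

    eps = rng.normal(0.0, np.sqrt(sc.sigma2_E), mean.shape)
    Y = mean + eps

    keep = np.ones(Y.shape, dtype=bool)
    if sc.dropout_prob > 0:
        keep = rng.random(Y.shape) >= sc.dropout_prob

    fam = np.repeat(cohort.family_ids, 2 * n_visits)
    ind = np.repeat(cohort.individual_ids.ravel(), n_visits)
    rec = pd.DataFrame(
        {
            "family_id": fam,
            "individual_id": ind,
            "zygosity": np.repeat(cohort.zygosity, 2 * n_visits),
            "sex": np.repeat(cohort.sex.ravel(), n_visits),
            "visit": np.tile(np.arange(1, n_visits + 1), 2 * n),
            "age_months": np.repeat(T, 2, axis=0).ravel(),
            "bmi": Y.reshape(-1),
            "genotype": np.repeat(geno.ravel(), n_visits),
            "exposure": np.repeat(env.ravel(), n_visits),
        }
    )
    return rec[keep.reshape(-1)].reset_index(drop=True)


def simulate_cohort_data(scenario: ScenarioConfig, seed=None):
    """Run the full generating chain for a scenario.

    Returns (cohort, genotypes, environments, records). Sub-seeds for each
    step are spawned from one generator so a single seed fixes the whole
    replicate.
    """
    rng = _as_rng(seed)
    cohort = generate_cohort(scenario.n_mz_pairs, scenario.n_dz_pairs, seed=rng)
    geno = simulate_genotypes(cohort, scenario.maf, seed=rng)
    env = simulate_environment(cohort, scenario.exposure_freq, seed=rng)
    rec = simulate_trajectories(cohort, geno, env, scenario, seed=rng)
    return cohort, geno, env, rec
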
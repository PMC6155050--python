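"""Synthetic GWAS summary statistics and biobank-style cohorts.

The two-sample generator draws per-SNP exposure effects gamma_j and direct
(pleiotropic) outcome effects alpha_j, sets Gamma_j = beta * gamma_j +
alpha_j, and observes both with GWAS estimation noise whose standard
errors follow the per-allele variance approximation
sigma = 1/sqrt(2 f (1-f) n); cross-sample error correlation emulates
participant overlap between the exposure and outcome GWAS.  The cohort
generator draws Binomial(2, f) genotypes, a linear exposure model with an
unobserved confounder, and Likert-style ordinal wellbeing outcomes, plus
age/sex/principal-component covariates with biobank-like moments.

Every generator returns a truth echo sufficient to recompute the expected
estimands analytically, so recovery tests never guess their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .prs_iv import Cohort

__all__ = [
    "SimulationTruth",
    "CohortSpec",
    "simulate_two_sample",
    "simulate_cohort",
    "PRESETS",
    "preset",
]

_BASES = np.array(list("ACGT"))
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationTruth:
    """Generating parameters for a two-sample summary-statistics dataset.

    ``invalid_fraction`` is the fraction of SNPs carrying a direct effect
    alpha_j drawn from the pleiotropy regime (1.0 = every SNP pleiotropic,
    the natural reading of the balanced/directional regimes); the chosen
    SNP identities are recorded in the truth echo.
    """

    true_beta: float = 0.0
    n_snps: int = 50
    gamma_mean: float = 0.1
    gamma_sd: float = 0.03
    gamma_min: float = 0.02
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    inside_slope: float = 0.0  # alpha-gamma coupling in the inside_violating regime
    invalid_fraction: float = 1.0
    n_exposure: int = 300_000
    n_outcome: int = 300_000
    overlap_rho: float = 0.0
    maf_low: float = 0.1
    maf_high: float = 0.5
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if not -1 <= self.overlap_rho <= 1:
            raise ValueError("overlap_rho must be in [-1, 1]")
        if self.pleiotropy not in {"none", "balanced", "directional", "inside_violating"}:
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")


def _allele_pairs(rng: np.random.Generator, j: int, palindromic_fraction: float):
    pal = rng.random(j) < palindromic_fraction
    ea, oa = [], []
    for is_pal in pal:
        pool = _PALINDROMIC if is_pal else _NONPALINDROMIC
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa), pal


def simulate_two_sample(truth: SimulationTruth, seed: int | None = None):
    """Generate matched exposure/outcome summary-statistics frames.

    Returns ``(exposure_df, outcome_df, echo)`` where the frames use the
    canonical summary-statistics columns and ``echo`` carries the drawn
    gamma, alpha, sigma arrays and the identities of the pleiotropic SNPs.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    j = truth.n_snps

    maf = rng.uniform(truth.maf_low, truth.maf_high, j)
    gamma = truth.gamma_mean + truth.gamma_sd * rng.standard_normal(j)
    gamma = np.maximum(gamma, truth.gamma_min)

    alpha = np.zeros(j)
    n_invalid = int(round(truth.invalid_fraction * j)) if truth.pleiotropy != "none" else 0
    invalid_idx = rng.choice(j, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    if truth.pleiotropy == "balanced":
        alpha[invalid_idx] = truth.sigma_alpha * rng.standard_normal(n_invalid)
    elif truth.pleiotropy == "directional":
        alpha[invalid_idx] = truth.mu_alpha + truth.sigma_alpha * rng.standard_normal(n_invalid)
    elif truth.pleiotropy == "inside_violating":
        dev = gamma[invalid_idx] - gamma.mean()
        alpha[invalid_idx] = (
            truth.mu_alpha
            + truth.inside_slope * dev
            + truth.sigma_alpha * rng.standard_normal(n_invalid)
        )

    Gamma = truth.true_beta * gamma + alpha

    sigma_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_exposure)
    sigma_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * truth.n_outcome)
    z1 = rng.standard_normal(j)
    z2 = truth.overlap_rho * z1 + np.sqrt(1 - truth.overlap_rho**2) * rng.standard_normal(j)
    gamma_hat = gamma + sigma_x * z1
    Gamma_hat = Gamma + sigma_y * z2

    ea, oa, pal = _allele_pairs(rng, j, truth.palindromic_fraction)
    # effect-allele frequency: the minor allele is the effect allele or not, at random
    flip_freq = rng.random(j) < 0.5
    eaf = np.where(flip_freq, 1 - maf, maf)
    chrom = (np.arange(j) % 22) + 1
    pos = 1_000_000 + (np.arange(j) // 22) * 25_000_000 + (np.arange(j) % 22) * 101

    snp = np.array([f"rs{100000 + i}" for i in range(j)])

    def frame(beta_hat, se):
        z = beta_hat / se
        pval = np.clip(2 * _norm_sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {
                "snp": snp,
                "chrom": chrom,
                "pos": pos,
                "ea": ea,
                "oa": oa,
                "eaf": eaf,
                "beta": beta_hat,
                "se": se,
                "pval": pval,
                "n": np.nan,
            }
        )

    exposure = frame(gamma_hat, sigma_x)
    outcome = frame(Gamma_hat, sigma_y)
    exposure["n"] = truth.n_exposure
    outcome["n"] = truth.n_outcome

    echo = {
        "truth": asdict(truth),
        "gamma": gamma,
        "alpha": alpha,
        "Gamma": Gamma,
        "sigma_x": sigma_x,
        "sigma_y": sigma_y,
        "maf": maf,
        "invalid_snps": list(snp[invalid_idx]),
        "palindromic_snps": list(snp[pal]),
    }
    return exposure, outcome, echo


def _norm_sf(z):
    from scipy.stats import norm

    return norm.sf(z)


@dataclass
class CohortSpec:
    """Generating parameters for an individual-level biobank-style cohort.

    Defaults emulate the follow-up setting: a 97-SNP score explaining
    about 1.8% of exposure variance, age ~ N(56.87, 8.00), 54% female,
    and a standard-normal unobserved confounder with effects ``confounder_exposure``
    on the exposure and ``confounder_outcome`` on the latent outcome, so
    the designed OLS bias is their product (exposure variance is 1).
    """

    n: int = 10_000
    n_snps: int = 97
    maf_low: float = 0.05
    maf_high: float = 0.5
    score_r2: float = 0.018
    true_beta: float = -0.035
    confounder_exposure: float = 0.5
    confounder_outcome: float = 0.3
    outcome_noise_sd: float = 1.0
    age_mean: float = 56.87
    age_sd: float = 8.00
    female_fraction: float = 0.54
    n_pcs: int = 10
    pc_exposure_leak: float = 0.0
    likert: bool = False
    likert_cutpoints: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.score_r2 < 1:
            raise ValueError("score_r2 must be in (0, 1)")


def simulate_cohort(spec: CohortSpec, seed: int | None = None):
    """Generate a cohort and its score weights.

    Returns ``(cohort, weights, echo)``: a :class:`~mrcausal.prs_iv.Cohort`
    with dosage columns, exposure, outcome(s) and covariates; a weights
    frame (snp_id, effect_allele, weight) whose weights are the true
    per-allele effects (an external-GWAS stand-in); and a truth echo.

    The exposure is built so its total variance is 1 with a genetic share
    of ``score_r2``: residual noise absorbs what the genetic component and
    confounder do not explain.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, k = spec.n, spec.n_snps

    maf = rng.uniform(spec.maf_low, spec.maf_high, k)
    dosages = rng.binomial(2, maf, size=(n, k)).astype(float)

    raw_effects = np.abs(rng.normal(1.0, 0.3, k))  # positive: "increasing" alleles
    geno_var = (raw_effects**2 * 2 * maf * (1 - maf)).sum()
    effects = raw_effects * np.sqrt(spec.score_r2 / geno_var)

    confounder = rng.standard_normal(n)
    resid_var = 1.0 - spec.score_r2 - spec.confounder_exposure**2
    if resid_var <= 0:
        raise ValueError("score_r2 + confounder_exposure^2 must be < 1")
    genetic = dosages @ effects
    exposure = (
        genetic
        + spec.confounder_exposure * confounder
        + np.sqrt(resid_var) * rng.standard_normal(n)
    )

    latent = (
        spec.true_beta * exposure
        + spec.confounder_outcome * confounder
        + spec.outcome_noise_sd * rng.standard_normal(n)
    )

    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    sex = (rng.random(n) < spec.female_fraction).astype(int)  # 1 = female
    pcs = rng.standard_normal((n, spec.n_pcs))
    if spec.pc_exposure_leak:
        exposure = exposure + spec.pc_exposure_leak * pcs[:, 0]

    snp_ids = [f"rs{200000 + i}" for i in range(k)]
    if spec.likert:
        cuts = spec.likert_cutpoints
        if cuts is None:
            # six roughly biobank-shaped categories with mean near 4.5
            scale = np.sqrt(np.var(latent))
            centre = latent.mean()
            cuts = tuple(centre + scale * c for c in (-2.2, -1.4, -0.6, 0.0, 1.0))
        outcome = (np.digitize(latent, cuts) + 1).astype(float)  # 1..6
    else:
        outcome = latent
    pc_names = [f"pc{i + 1}" for i in range(spec.n_pcs)]
    data = pd.DataFrame(
        np.column_stack([dosages, exposure, outcome, age, sex.astype(float), pcs]),
        columns=snp_ids + ["exposure", "outcome", "age", "sex"] + pc_names,
    )

    cohort = Cohort(
        data=data,
        dosage_cols=snp_ids,
        dosage_effect_allele={s: "A" for s in snp_ids},
        exposure="exposure",
        outcomes=["outcome"],
        covariates=["age", "sex"] + [f"pc{i + 1}" for i in range(spec.n_pcs)],
    )
    weights = pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": "A", "weight": effects}
    )
    echo = {
        "spec": asdict(spec),
        "effects": effects,
        "maf": maf,
        "ols_bias": spec.confounder_exposure * spec.confounder_outcome,
        "exposure_variance": 1.0,
    }
    return cohort, weights, echo


#: named scenario presets mirroring the study's two instrument regimes
PRESETS: dict[str, SimulationTruth] = {
    # strong 97-SNP adiposity-type instrument, genome-wide threshold
    "bmi_to_swb": SimulationTruth(
        true_beta=-0.045,
        n_snps=97,
        gamma_mean=0.025,
        gamma_sd=0.01,
        gamma_min=0.012,
        n_exposure=339_000,
        n_outcome=298_000,
        palindromic_fraction=0.1,
    ),
    # weaker 84-SNP wellbeing-type instrument at the liberal threshold
    "swb_to_cmh": SimulationTruth(
        true_beta=0.0,
        n_snps=84,
        gamma_mean=0.015,
        gamma_sd=0.006,
        gamma_min=0.008,
        n_exposure=298_000,
        n_outcome=339_000,
        palindromic_fraction=0.1,
    ),
}


def preset(name: str, **overrides) -> SimulationTruth:
    """A copy of a named preset with optional field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    base = asdict(PRESETS[name])
    base.update(overrides)
    return SimulationTruth(**base)
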
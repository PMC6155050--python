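"""Monte-Carlo operating characteristics of the MR estimators and diagnostics.

Each study here simulates a named data-generating regime, runs the full
method under test, and summarises its behaviour (CI coverage, type-I
error, bias, breakdown, detection rate).  The studies are used both by the
test suite and by the reproduction script, so every number they report is
recomputed from scratch on demand.

The flagship regimes:

* ``null_coverage`` — no pleiotropy, 50 strong instruments: every
  estimator's 95% CI should cover the truth at close to nominal rate.
* ``balanced`` / ``directional`` pleiotropy — IVW stays unbiased under
  balanced pleiotropy; under directional pleiotropy IVW is biased while
  the Egger slope stays near the truth and the Egger intercept estimates
  the mean direct effect.
* weighted-median breakdown at 49% vs 60% invalid weight.
* SIMEX attenuation correction when the NOME assumption fails.
* MR-PRESSO global type-I error and planted-outlier recovery.
* 2SLS confounding robustness on the synthetic cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import estimators as est
from . import prs_iv
from . import summary_data as sd
from .synthetic import CohortSpec, SimulationTruth, simulate_cohort, simulate_two_sample

__all__ = [
    "instrument_frame",
    "harmonised_instruments",
    "coverage_study",
    "pleiotropy_bias_study",
    "median_breakdown_study",
    "simex_study",
    "q_type1_study",
    "presso_type1_study",
    "presso_outlier_study",
    "cohort_iv_study",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def instrument_frame(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Fast instrument table for generator output that is already allele-aligned.

    Merges the two summary frames on SNP id and applies the same
    exposure-positive orientation ``harmonise`` would; used inside large
    simulation loops where the allele bookkeeping is known to be trivial.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    gamma = merged["beta_x"].to_numpy(float)
    Gamma = merged["beta_y"].to_numpy(float)
    flip = gamma < 0
    return pd.DataFrame(
        {
            "snp": merged["snp"],
            "gamma_hat": np.where(flip, -gamma, gamma),
            "sigma_x": merged["se_x"].to_numpy(float),
            "Gamma_hat": np.where(flip, -Gamma, Gamma),
            "sigma_y": merged["se_y"].to_numpy(float),
        }
    )


def harmonised_instruments(
    truth: SimulationTruth, seed: int, p_threshold: float = 5e-8
) -> pd.DataFrame:
    """One simulated replicate pushed through the real selection/harmonisation path."""
    exposure, outcome, _ = simulate_two_sample(truth, seed=seed)
    selected = sd.select_instruments(exposure, p_threshold)
    return sd.retained(sd.harmonise(selected, outcome))


NULL_COVERAGE_TRUTH = SimulationTruth(
    true_beta=0.1,
    n_snps=50,
    gamma_mean=0.1,
    gamma_sd=0.03,
    gamma_min=0.02,
    pleiotropy="none",
    n_exposure=300_000,
    n_outcome=300_000,
    palindromic_fraction=0.0,
)


def coverage_study(
    n_reps: int = 1000,
    seed: int = 0,
    truth: SimulationTruth = NULL_COVERAGE_TRUTH,
    n_boot: int = 200,
) -> dict:
    """95% CI coverage and bias of all four estimators under valid instruments.

    Runs the full select-harmonise-estimate path per replicate.  The
    bootstrap for the median/mode SEs uses ``n_boot`` draws per replicate.
    """
    seeds = _child_seeds(seed, n_reps)
    covered = {m: 0 for m in ("ivw", "egger", "weighted_median", "weighted_mode")}
    estimates = {m: [] for m in covered}
    for i in range(n_reps):
        instr = harmonised_instruments(truth, int(seeds[i]))
        results = {
            "ivw": est.ivw(instr),
            "egger": est.egger(instr),
            "weighted_median": est.weighted_median(
                instr, n_boot=n_boot, seed=int(seeds[i]) + 1
            ),
            "weighted_mode": est.weighted_mode(instr, n_boot=n_boot, seed=int(seeds[i]) + 2),
        }
        for m, e in results.items():
            estimates[m].append(e.beta)
            if e.ci_low <= truth.true_beta <= e.ci_high:
                covered[m] += 1
    return {
        "true_beta": truth.true_beta,
        "n_reps": n_reps,
        "coverage": {m: covered[m] / n_reps for m in covered},
        "bias": {m: float(np.mean(estimates[m]) - truth.true_beta) for m in estimates},
    }


def pleiotropy_bias_study(
    regime: str,
    n_reps: int = 1000,
    seed: int = 0,
    true_beta: float = 0.1,
    mu_alpha: float = 0.02,
    sigma_alpha: float = 0.01,
) -> dict:
    """Mean IVW and Egger behaviour under balanced or directional pleiotropy.

    Every SNP carries a direct effect alpha_j ~ normal(mu, sigma) (mu = 0
    in the balanced regime); InSIDE holds because alpha is drawn
    independently of gamma.
    """
    mu = 0.0 if regime == "balanced" else mu_alpha
    truth = SimulationTruth(
        true_beta=true_beta,
        n_snps=50,
        pleiotropy=regime,
        mu_alpha=mu,
        sigma_alpha=sigma_alpha,
        invalid_fraction=1.0,
        palindromic_fraction=0.0,
    )
    seeds = _child_seeds(seed, n_reps)
    ivw_b, egger_b, egger_i = [], [], []
    for i in range(n_reps):
        exposure, outcome, _ = simulate_two_sample(truth, seed=int(seeds[i]))
        instr = instrument_frame(exposure, outcome)
        ivw_b.append(est.ivw(instr).beta)
        fit = est.EggerRegression().fit(instr)
        egger_b.append(fit.beta_)
        egger_i.append(fit.intercept_)
    return {
        "regime": regime,
        "n_reps": n_reps,
        "true_beta": true_beta,
        "mu_alpha": mu,
        "ivw_bias": float(np.mean(ivw_b) - true_beta),
        "egger_slope_bias": float(np.mean(egger_b) - true_beta),
        "egger_intercept_bias": float(np.mean(egger_i) - mu),
    }


def median_breakdown_study(
    invalid_fraction: float,
    n_reps: int = 200,
    seed: int = 0,
    true_beta: float = 0.2,
    alpha_invalid: float = 0.1,
    n_snps: int = 100,
) -> dict:
    """Weighted-median estimate with a given fraction of invalid weight.

    Instruments share a common exposure effect and allele frequency so
    every SNP carries (almost) equal weight; invalid SNPs all receive the
    same positive direct effect.  Large GWAS sample sizes keep the
    estimation noise small so the 50% breakdown boundary is sharp.
    """
    rng_seeds = _child_seeds(seed, n_reps)
    gamma = 0.1
    maf = 0.3
    n_gwas = 50_000_000  # noise small relative to the invalid offset
    sigma = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_gwas)
    n_invalid = int(round(invalid_fraction * n_snps))
    estimates = []
    for i in range(n_reps):
        rng = np.random.default_rng(int(rng_seeds[i]))
        alpha = np.zeros(n_snps)
        alpha[:n_invalid] = alpha_invalid
        gamma_hat = gamma + sigma * rng.standard_normal(n_snps)
        Gamma_hat = true_beta * gamma + alpha + sigma * rng.standard_normal(n_snps)
        instr = pd.DataFrame(
            {
                "snp": [f"rs{j}" for j in range(n_snps)],
                "gamma_hat": gamma_hat,
                "sigma_x": sigma,
                "Gamma_hat": Gamma_hat,
                "sigma_y": sigma,
            }
        )
        wr = est.wald_ratios(instr)
        estimates.append(
            est.weighted_median_point(wr["ratio"].to_numpy(), wr["weight"].to_numpy())
        )
    estimates = np.array(estimates)
    return {
        "invalid_fraction": invalid_fraction,
        "true_beta": true_beta,
        "n_reps": n_reps,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
    }


SIMEX_TRUTH = SimulationTruth(
    true_beta=0.4,
    n_snps=100,
    gamma_mean=0.05,
    gamma_sd=0.02,
    gamma_min=0.005,
    pleiotropy="none",
    n_exposure=5_000,  # noisy exposure GWAS: NOME fails badly (I2_GX ~ 0.35)
    n_outcome=300_000,
    palindromic_fraction=0.0,
)


def simex_study(n_reps: int = 200, seed: int = 0, B: int = 200) -> dict:
    """How often SIMEX moves the Egger slope closer to the truth under NOME failure."""
    seeds = _child_seeds(seed, n_reps)
    closer = 0
    i2_values, naive_err, corrected_err = [], [], []
    for i in range(n_reps):
        exposure, outcome, _ = simulate_two_sample(SIMEX_TRUTH, seed=int(seeds[i]))
        instr = instrument_frame(exposure, outcome)
        i2_values.append(diag.i2_gx(instr).i2_gx)
        naive = est.egger(instr)
        corrected = diag.egger_simex(instr, B=B, seed=int(seeds[i]) + 1)
        ne = abs(naive.beta - SIMEX_TRUTH.true_beta)
        ce = abs(corrected.beta - SIMEX_TRUTH.true_beta)
        naive_err.append(ne)
        corrected_err.append(ce)
        if ce < ne:
            closer += 1
    return {
        "n_reps": n_reps,
        "true_beta": SIMEX_TRUTH.true_beta,
        "mean_i2_gx": float(np.mean(i2_values)),
        "improvement_fraction": closer / n_reps,
        "mean_naive_abs_error": float(np.mean(naive_err)),
        "mean_corrected_abs_error": float(np.mean(corrected_err)),
    }


def q_type1_study(n_reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Cochran's Q rejection rate under a homogeneous (no-pleiotropy) null."""
    truth = SimulationTruth(
        true_beta=0.0, n_snps=50, pleiotropy="none", palindromic_fraction=0.0
    )
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for i in range(n_reps):
        exposure, outcome, _ = simulate_two_sample(truth, seed=int(seeds[i]))
        instr = instrument_frame(exposure, outcome)
        if diag.cochran_q(instr).pval < alpha:
            rejections += 1
    return {"n_reps": n_reps, "alpha": alpha, "rejection_rate": rejections / n_reps}


def presso_type1_study(
    n_reps: int = 500, seed: int = 0, n_sim: int = 1000, sig: float = 0.05
) -> dict:
    """MR-PRESSO global-test rejection rate under the no-pleiotropy null."""
    truth = SimulationTruth(
        true_beta=0.1, n_snps=20, pleiotropy="none", palindromic_fraction=0.0
    )
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for i in range(n_reps):
        exposure, outcome, _ = simulate_two_sample(truth, seed=int(seeds[i]))
        instr = instrument_frame(exposure, outcome)
        presso = diag.mr_presso(instr, n_sim=n_sim, seed=int(seeds[i]) + 1, sig=sig)
        if presso.global_pval < sig:
            rejections += 1
    return {"n_reps": n_reps, "sig": sig, "rejection_rate": rejections / n_reps}


def presso_outlier_study(
    n_reps: int = 200, seed: int = 0, n_sim: int = 1000, n_snps: int = 50
) -> dict:
    """Recovery rate of a single planted pleiotropic outlier by MR-PRESSO.

    The planted SNP's direct effect inflates its Wald ratio to ten times
    the median ratio; with 50 instruments the resulting shift of the
    leave-one-out estimates stays small enough that only the planted SNP
    should be flagged.
    """
    truth = SimulationTruth(
        true_beta=0.2, n_snps=n_snps, pleiotropy="none", palindromic_fraction=0.0
    )
    seeds = _child_seeds(seed, n_reps)
    detected = 0
    false_extra = 0
    for i in range(n_reps):
        exposure, outcome, echo = simulate_two_sample(truth, seed=int(seeds[i]))
        rng = np.random.default_rng(int(seeds[i]) + 7)
        planted = int(rng.integers(n_snps))
        outcome = outcome.copy()
        # push the planted ratio from beta to 10 * beta
        outcome.loc[planted, "beta"] += 9 * truth.true_beta * echo["gamma"][planted]
        instr = instrument_frame(exposure, outcome)
        presso = diag.mr_presso(instr, n_sim=n_sim, seed=int(seeds[i]) + 1)
        if exposure.loc[planted, "snp"] in presso.outliers:
            detected += 1
        false_extra += len(set(presso.outliers) - {exposure.loc[planted, "snp"]})
    return {
        "n_reps": n_reps,
        "detection_rate": detected / n_reps,
        "mean_false_flags": false_extra / n_reps,
    }


def cohort_iv_study(
    n_reps: int = 1000, seed: int = 0, spec: CohortSpec | None = None
) -> dict:
    """OLS vs 2SLS on the confounded synthetic cohort, plus first-stage recovery.

    The designed OLS bias is confounder_exposure * confounder_outcome
    (unit exposure variance), so the study reports both the recovered
    causal effect and how far OLS lands from it.
    """
    spec = spec or CohortSpec()
    seeds = _child_seeds(seed, n_reps)
    tsls, ols, r2s, fstats = [], [], [], []
    for i in range(n_reps):
        cohort, weights, _ = simulate_cohort(spec, seed=int(seeds[i]))
        score = prs_iv.build_score(cohort, weights)
        fs = prs_iv.first_stage(cohort, score, cohort.covariates)
        obs = prs_iv.observational_regression(cohort, "outcome", cohort.covariates)
        ivr = prs_iv.iv_regression(cohort, "outcome", score, cohort.covariates)
        tsls.append(ivr.beta)
        ols.append(obs.beta)
        r2s.append(fs.r2)
        fstats.append(fs.f_stat)
    return {
        "n_reps": n_reps,
        "n": spec.n,
        "true_beta": spec.true_beta,
        "designed_ols_bias": spec.confounder_exposure * spec.confounder_outcome,
        "mean_tsls": float(np.mean(tsls)),
        "mean_ols": float(np.mean(ols)),
        "mean_first_stage_r2": float(np.mean(r2s)),
        "mean_first_stage_f": float(np.mean(fstats)),
        "target_first_stage_r2": spec.score_r2,
    }
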
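"""Heterogeneity, pleiotropy, measurement-error, outlier and power diagnostics.

These qualify the causal estimates: Cochran's Q / I-squared for
heterogeneity of per-SNP Wald ratios, the regression-dilution I2_GX
statistic (NOME assumption) with a SIMEX-corrected Egger fit when it falls
below 0.9, the MR-PRESSO residual-sum-of-squares global/outlier/distortion
tests, leave-one-out influence analysis, funnel-plot data with a simple
asymmetry test, and asymptotic power for a two-sample MR design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerRegression,
    IVWEstimator,
    MREstimate,
    Z95,
    instrument_table,
    ivw,
    wald_ratios,
)

__all__ = [
    "HeterogeneityReport",
    "NOMEReport",
    "PressoReport",
    "PowerEstimate",
    "FunnelReport",
    "cochran_q",
    "i2_gx",
    "egger_simex",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
    "mr_power",
]

SIMEX_TRIGGER = 0.9  # regression-dilution threshold below which SIMEX is applied


@dataclass
class HeterogeneityReport:
    Q: float
    df: int
    pval: float
    i2: float


@dataclass
class NOMEReport:
    i2_gx: float
    simex_triggered: bool
    degenerate: bool = False


@dataclass
class PressoReport:
    global_rss: float
    global_pval: float
    outlier_pvals: dict = field(default_factory=dict)
    outliers: list = field(default_factory=list)
    corrected: MREstimate | None = None
    distortion_pval: float | None = None
    report_corrected: bool = False


@dataclass
class PowerEstimate:
    n_outcome: int
    r2_instrument: float
    beta_target: float
    alpha: float
    power: float


@dataclass
class FunnelReport:
    table: pd.DataFrame = field(repr=False)
    asymmetry_slope: float | None = None
    asymmetry_se: float | None = None
    asymmetry_pval: float | None = None


def cochran_q(instruments, beta_ref: float | None = None) -> HeterogeneityReport:
    """Cochran's Q of the Wald ratios about ``beta_ref`` (default: fixed-effect IVW).

    Q = sum w_j (ratio_j - beta_ref)^2 with w_j the inverse-variance
    weights; p from chi-square with J-1 df; I2 = max(0, (Q - df)/Q).
    """
    wr = wald_ratios(instruments)
    r, w = wr["ratio"].to_numpy(), wr["weight"].to_numpy()
    if len(r) < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    if beta_ref is None:
        beta_ref = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_ref) ** 2))
    df = len(r) - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport(q, df, pval, i2)


def i2_gx(instruments) -> NOMEReport:
    """Regression-dilution I2_GX: how far NOME holds for the exposure betas.

    With v_j = sigma_x^-2 and Q_GX the weighted dispersion of the
    gamma_hat, I2_GX = (Q_GX - (J-1))/Q_GX.  Values near 1 mean exposure
    measurement error is negligible relative to instrument spread; below
    0.9 the Egger slope is attenuated enough that SIMEX correction is
    applied.
    """
    tab = instrument_table(instruments)
    g = tab["gamma_hat"].to_numpy(float)
    v = 1.0 / tab["sigma_x"].to_numpy(float) ** 2
    j = len(g)
    if j < 2:
        raise ValueError("I2_GX needs at least 2 SNPs")
    gbar = float(np.sum(v * g) / np.sum(v))
    q_gx = float(np.sum(v * (g - gbar) ** 2))
    if q_gx == 0.0:
        warnings.warn("Q_GX = 0 (all weighted gamma_hat identical): I2_GX undefined")
        return NOMEReport(np.nan, False, degenerate=True)
    stat = (q_gx - (j - 1)) / q_gx
    return NOMEReport(float(stat), bool(stat < SIMEX_TRIGGER))


def _vectorised_egger(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted Egger fits for a batch of designs.

    ``x`` has shape (B, J); ``y`` and ``w`` shape (J,).  Returns slope,
    intercept, and overdispersion-inflated slope/intercept variances, each
    of shape (B,).
    """
    j = x.shape[1]
    sw = w.sum()
    swy = (w * y).sum()
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    swxy = (w * x * y).sum(axis=1)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y[None, :] - intercept[:, None] - slope[:, None] * x
    rss_w = (w * resid**2).sum(axis=1)
    infl = np.maximum(1.0, rss_w / (j - 2))
    return slope, intercept, (sw / det) * infl, (swxx / det) * infl


def quadratic_extrapolate(lam, values, at: float = -1.0) -> float:
    """Least-squares quadratic in lambda evaluated at ``at`` (the SIMEX extrapolant)."""
    coef = np.polyfit(np.asarray(lam, float), np.asarray(values, float), 2)
    return float(np.polyval(coef, at))


def egger_simex(
    instruments,
    lambdas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
    B: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """SIMEX-corrected MR-Egger under exposure measurement error.

    For each lambda > 0, B pseudo-datasets add normal(0, lambda*sigma_x^2)
    noise to every gamma_hat and the Egger slope/intercept are averaged
    across the B fits.  A quadratic in lambda is fitted through the naive
    (lambda = 0) and inflated estimates and extrapolated to lambda = -1,
    the zero-measurement-error limit.  Variances are extrapolated the same
    way (per-lambda model variance plus between-simulation variance; naive
    variance at lambda 0), falling back to the naive SE when the
    extrapolated variance is non-positive.
    """
    if seed is None:
        raise ValueError("seed is mandatory for SIMEX")
    if B < 100:
        raise ValueError("B < 100 makes the extrapolation unstable; refuse")
    tab = instrument_table(instruments)
    naive = EggerRegression().fit(tab)
    lam = np.array(sorted({0.0, *lambdas}))
    if len(lam) < 3:
        # degenerate grid: nothing to extrapolate
        est = naive.estimate_
        est.method = "egger_simex"
        est.extras.update({"lambdas": list(lam), "B": B, "degenerate_grid": True})
        return est

    x = tab["gamma_hat"].to_numpy(float)
    y = tab["Gamma_hat"].to_numpy(float)
    sx = tab["sigma_x"].to_numpy(float)
    w = 1.0 / tab["sigma_y"].to_numpy(float) ** 2
    j = len(x)
    rng = np.random.default_rng(seed)

    mean_slope, mean_int = [], []
    var_slope, var_int = [], []
    for lm in lam:
        if lm == 0.0:
            mean_slope.append(naive.beta_)
            mean_int.append(naive.intercept_)
            var_slope.append(naive.se_**2)
            var_int.append(naive.intercept_se_**2)
            continue
        noise = np.sqrt(lm) * sx * rng.standard_normal((B, j))
        s, c, vs, vc = _vectorised_egger(x + noise, y, w)
        mean_slope.append(s.mean())
        mean_int.append(c.mean())
        var_slope.append(vs.mean() + s.var(ddof=1))
        var_int.append(vc.mean() + c.var(ddof=1))

    beta = quadratic_extrapolate(lam, mean_slope)
    intercept = quadratic_extrapolate(lam, mean_int)
    var_b = quadratic_extrapolate(lam, var_slope)
    var_i = quadratic_extrapolate(lam, var_int)
    se = float(np.sqrt(var_b)) if var_b > 0 else float(naive.se_)
    int_se = float(np.sqrt(var_i)) if var_i > 0 else float(naive.intercept_se_)
    tdist = stats.t(j - 2)
    tcrit = tdist.ppf(0.975)
    return MREstimate(
        method="egger_simex",
        beta=beta,
        se=se,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        pval=float(2 * tdist.sf(abs(beta) / se)),
        n_snp=j,
        extras={
            "intercept": intercept,
            "intercept_se": int_se,
            "intercept_pval": float(2 * tdist.sf(abs(intercept) / int_se)),
            "lambdas": [float(v) for v in lam],
            "B": B,
            "naive_beta": float(naive.beta_),
            "naive_intercept": float(naive.intercept_),
        },
    )


def _loo_ivw_betas(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorised over SNPs."""
    sw, swr = w.sum(), (w * r).sum()
    return (swr - w * r) / (sw - w)


def mr_presso(
    instruments,
    n_sim: int = 1000,
    seed: int | None = None,
    sig: float = 0.05,
) -> PressoReport:
    """MR-PRESSO residual-sum-of-squares pleiotropy tests.

    Global test: per-SNP leave-one-out IVW residual RSS_j summed and
    compared with a parametric null (outcome betas redrawn around the
    leave-one-out predictions).  Outlier test: per-SNP empirical p-values
    (Bonferroni-adjusted) of RSS_j against the simulated counterpart.
    Distortion test: bootstrap over the non-outlier set comparing the
    outlier-corrected IVW estimate with the full-set estimate.  Empirical
    p-values use (1 + exceedances)/(1 + n_sim) so they are never exactly 0.
    The corrected estimate is flagged for reporting when both the global
    and distortion tests are significant at ``sig``.
    """
    if seed is None:
        raise ValueError("seed is mandatory for MR-PRESSO")
    tab = instrument_table(instruments)
    j = len(tab)
    if j < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    g = tab["gamma_hat"].to_numpy(float)
    G = tab["Gamma_hat"].to_numpy(float)
    sy = tab["sigma_y"].to_numpy(float)
    snps = tab["snp"].to_numpy()
    r = G / g
    w = (g / sy) ** 2  # = ratio_se^-2

    beta_loo = _loo_ivw_betas(r, w)
    rss_obs = w * (G - beta_loo * g) ** 2
    global_obs = float(rss_obs.sum())

    rng = np.random.default_rng(seed)
    G_star = beta_loo * g + sy * rng.standard_normal((n_sim, j))
    r_star = G_star / g
    sw = w.sum()
    swr_star = (w * r_star).sum(axis=1)
    beta_loo_star = (swr_star[:, None] - w * r_star) / (sw - w)
    rss_star = w * (G_star - beta_loo_star * g) ** 2
    global_star = rss_star.sum(axis=1)

    global_pval = float((1 + np.sum(global_star >= global_obs)) / (1 + n_sim))
    raw_p = (1 + (rss_star >= rss_obs).sum(axis=0)) / (1 + n_sim)
    adj_p = np.minimum(1.0, raw_p * j)  # Bonferroni
    outlier_mask = adj_p < sig
    outlier_pvals = {str(s): float(p) for s, p in zip(snps, adj_p)}
    outliers = [str(s) for s in snps[outlier_mask]]

    if outlier_mask.all():
        raise ValueError("every SNP flagged as an outlier: no corrected estimate possible")

    keep = ~outlier_mask
    full = ivw(tab)
    corrected = ivw(tab.loc[keep]) if outlier_mask.any() else full

    distortion_pval = None
    if outlier_mask.any():
        idx = np.nonzero(keep)[0]
        n_keep = len(idx)
        draws = rng.integers(0, n_keep, size=(1000, n_keep))
        sampled = idx[draws]
        wb = w[sampled]
        rb = r[sampled]
        beta_b = (wb * rb).sum(axis=1) / wb.sum(axis=1)
        d_obs = abs(full.beta - corrected.beta)
        distortion_pval = float(
            (1 + np.sum(np.abs(beta_b - corrected.beta) >= d_obs)) / (1 + len(beta_b))
        )
    report_corrected = (
        outlier_mask.any()
        and global_pval < sig
        and distortion_pval is not None
        and distortion_pval < sig
    )
    return PressoReport(
        global_rss=global_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        corrected=corrected,
        distortion_pval=distortion_pval,
        report_corrected=bool(report_corrected),
    )


def leave_one_out(instruments) -> pd.DataFrame:
    """IVW recomputed excluding each SNP in turn, most influential first."""
    tab = instrument_table(instruments)
    if len(tab) < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    full = ivw(tab)
    rows = []
    for i in range(len(tab)):
        sub = tab.drop(index=i)
        est = ivw(sub)
        rows.append(
            {
                "snp_excluded": tab.loc[i, "snp"],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "delta": abs(est.beta - full.beta),
            }
        )
    out = pd.DataFrame(rows).sort_values("delta", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def funnel_data(instruments) -> FunnelReport:
    """Per-SNP ratio vs precision, with a precision-weighted asymmetry test.

    The asymmetry statistic is the slope of the weighted regression of the
    Wald ratio on its precision (1/SE); under symmetric scatter it is
    centred on zero.  No test with fewer than 3 SNPs.
    """
    wr = wald_ratios(instruments)
    table = pd.DataFrame(
        {"snp": wr["snp"], "ratio": wr["ratio"], "precision": 1.0 / wr["ratio_se"]}
    )
    if len(table) < 3:
        return FunnelReport(table)
    x = table["precision"].to_numpy()
    y = table["ratio"].to_numpy()
    w = wr["weight"].to_numpy()
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    s2 = (w * resid**2).sum() / (len(y) - 2)
    slope_se = float(np.sqrt(s2 * sw / det))
    tdist = stats.t(len(y) - 2)
    pval = float(2 * tdist.sf(abs(slope) / slope_se)) if slope_se > 0 else 1.0
    return FunnelReport(table, float(slope), slope_se, pval)


def mr_power(
    n_outcome: int,
    r2_instrument: float,
    beta_target: float,
    alpha: float = 0.05,
    case_fraction: float | None = None,
) -> PowerEstimate:
    """Asymptotic two-sided power of a two-sample MR test.

    Non-centrality NCP = n * R2 * beta^2 for a continuous outcome, scaled
    by case_fraction*(1 - case_fraction) for a binary one; power is the
    probability a |Z| test at level alpha rejects given the shifted normal.
    """
    if not 0 < r2_instrument < 1:
        raise ValueError("r2_instrument must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ncp = n_outcome * r2_instrument * beta_target**2
    if case_fraction is not None:
        ncp *= case_fraction * (1 - case_fraction)
    z = stats.norm.ppf(1 - alpha / 2)
    shift = np.sqrt(ncp)
    power = float(stats.norm.sf(z - shift) + stats.norm.cdf(-z - shift))
    return PowerEstimate(n_outcome, r2_instrument, beta_target, alpha, power)
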
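"""One-sample follow-up: weighted allele score, instrument strength, and 2SLS.

A weighted polygenic score (external GWAS betas x effect-allele dosages,
standardised to mean 0 / SD 1) instruments the exposure in a two-stage
least-squares regression with age, sex and principal-component covariates;
instrument strength is reported as the score's partial F and incremental
R-squared from the first stage, and estimates can be re-run within sex or
median-age strata.

``TwoStageLeastSquares`` follows the scikit-learn estimator protocol
(init parameters, ``fit``, trailing-underscore attributes); Likert-coded
outcomes are treated numerically, with "don't know"-style categories
already coded missing upstream, and every model is complete-case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "Cohort",
    "EffectEstimate",
    "FirstStageResult",
    "IVResult",
    "build_score",
    "first_stage",
    "observational_regression",
    "TwoStageLeastSquares",
    "iv_regression",
    "stratified_iv",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class Cohort:
    """An individual-level analysis table plus its column roles.

    ``data`` holds one row per individual; dosage columns contain additive
    genotype dosages in [0, 2] counting ``dosage_effect_allele[snp]``.
    """

    data: pd.DataFrame = field(repr=False)
    dosage_cols: list = field(default_factory=list)
    dosage_effect_allele: dict = field(default_factory=dict)
    exposure: str = "exposure"
    outcomes: list = field(default_factory=lambda: ["outcome"])
    covariates: list = field(default_factory=list)

    def __post_init__(self):
        if self.dosage_cols:
            vals = self.data[self.dosage_cols].to_numpy(float)
            if ((vals < 0) | (vals > 2)).any():
                raise ValueError("dosage entries must lie in [0, 2]")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EffectEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_used: int


@dataclass
class FirstStageResult:
    f_stat: float
    df_denom: int
    r2: float
    pval: float
    n_used: int


@dataclass
class IVResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    first_stage_F: float
    first_stage_r2: float
    n_used: int
    weak_instrument: bool = False


def build_score(cohort: Cohort, weights: pd.DataFrame, *, max_missing: float = 0.2) -> pd.Series:
    """Weighted allele score, standardised to mean 0 and SD 1.

    ``weights`` columns: ``snp_id, effect_allele, weight`` (external GWAS
    betas).  A weight whose effect allele is the opposite of the dosage
    coding contributes ``w * (2 - g)``, which after standardisation equals
    the sign-flipped alignment.  Weight SNPs absent from the cohort are
    excluded with a warning; more than ``max_missing`` of them missing is
    an error (the score would not represent the published instrument).
    """
    dosage_set = set(cohort.dosage_cols) & set(cohort.data.columns)
    in_cohort = weights["snp_id"].isin(dosage_set)
    missing = list(weights.loc[~in_cohort, "snp_id"])
    used = weights.loc[in_cohort]
    aligned = np.array(
        [
            row["effect_allele"] == cohort.dosage_effect_allele.get(row["snp_id"])
            for _, row in used.iterrows()
        ]
    )
    g = cohort.data[list(used["snp_id"])].to_numpy(float)
    w = used["weight"].to_numpy(float)
    if len(used):
        # misaligned weights contribute w * (2 - g) = -w * g + 2w
        contributions = g @ np.where(aligned, w, -w) + 2.0 * w[~aligned].sum()
    else:
        contributions = np.zeros(len(cohort))
    if missing:
        frac = len(missing) / len(weights)
        if frac > max_missing:
            raise ValueError(
                f"{len(missing)}/{len(weights)} score SNPs missing from cohort "
                f"({frac:.0%} > {max_missing:.0%})"
            )
        warnings.warn(f"{len(missing)} score SNP(s) missing from cohort: excluded")
    score = pd.Series(contributions, index=cohort.data.index, name="score")
    sd = score.std(ddof=0)
    if sd == 0:
        raise ValueError("allele score has zero variance")
    return (score - score.mean()) / sd


def _design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    x = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])
    return x


def _check_collinear(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    rank = 1
    offenders = []
    for i in range(1, x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : i + 1])
        if new_rank == rank:
            offenders.append(names[i - 1])
        rank = new_rank
    raise ValueError(f"collinear covariate column(s): {', '.join(offenders)}")


def _complete_cases(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    df = data[columns].apply(pd.to_numeric, errors="coerce")
    df = df.dropna()
    if len(df) < 30:
        raise ValueError(f"only {len(df)} complete cases; need at least 30")
    return df


def first_stage(
    cohort: Cohort,
    score: pd.Series,
    covariates: list[str] | None = None,
) -> FirstStageResult:
    """Instrument strength: partial F and incremental R2 of the score.

    Regresses the exposure on the score (plus covariates when given) and
    reports the score's 1-df partial F and the R2 gained over the
    covariate-only model.
    """
    covariates = list(covariates or [])
    work = cohort.data[[cohort.exposure] + covariates].copy()
    work["_score"] = score
    df = _complete_cases(work, [cohort.exposure, "_score"] + covariates)
    if df["_score"].std(ddof=0) == 0:
        raise ValueError("score has zero variance on the analysis sample")
    y = df[cohort.exposure].to_numpy(float)
    x_full = _design(df, ["_score"] + covariates)
    _check_collinear(x_full, ["_score"] + covariates)
    beta_full, rss_full = _ols_rss(x_full, y)
    x_red = _design(df, covariates)
    _, rss_red = _ols_rss(x_red, y)
    n, k = len(y), x_full.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    r2_incremental = (rss_red - rss_full) / tss
    df_denom = n - k
    f_stat = float((rss_red - rss_full) / (rss_full / df_denom))
    pval = float(stats.f.sf(f_stat, 1, df_denom))
    return FirstStageResult(f_stat, df_denom, float(r2_incremental), pval, n)


def _ols_rss(x: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def observational_regression(
    cohort: Cohort,
    outcome: str,
    covariates: list[str] | None = None,
) -> EffectEstimate:
    """OLS of the outcome on the exposure plus covariates (complete cases)."""
    covariates = list(covariates or [])
    cols = [outcome, cohort.exposure] + covariates
    df = _complete_cases(cohort.data, cols)
    y = df[outcome].to_numpy(float)
    names = [cohort.exposure] + covariates
    x = _design(df, names)
    _check_collinear(x, names)
    beta, rss = _ols_rss(x, y)
    n, k = len(y), x.shape[1]
    sigma2 = rss / (n - k)
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    tdist = stats.t(n - k)
    tcrit = tdist.ppf(0.975)
    return EffectEstimate(
        beta=b,
        se=se,
        ci_low=b - tcrit * se,
        ci_high=b + tcrit * se,
        pval=float(2 * tdist.sf(abs(b) / se)),
        n_used=n,
    )


class TwoStageLeastSquares(BaseEstimator):
    """Two-stage least squares with a single instrument and exogenous covariates.

    Stage 1 regresses the exposure on the instrument and covariates; stage
    2 regresses the outcome on the fitted exposure and covariates, with
    the conventional 2SLS covariance (structural residuals, homoskedastic
    by default, heteroskedasticity-robust with ``robust=True``).  A first-
    stage partial F below ``weak_f_threshold`` triggers a prominent weak-
    instrument warning but never suppresses the estimate.
    """

    def __init__(self, robust: bool = False, weak_f_threshold: float = 10.0):
        self.robust = robust
        self.weak_f_threshold = weak_f_threshold

    def fit(
        self,
        cohort: Cohort,
        outcome: str,
        instrument: pd.Series,
        covariates: list[str] | None = None,
    ):
        covariates = list(covariates or [])
        work = cohort.data[[outcome, cohort.exposure] + covariates].copy()
        work["_iv"] = instrument
        df = _complete_cases(work, [outcome, cohort.exposure, "_iv"] + covariates)
        y = df[outcome].to_numpy(float)
        x_names = [cohort.exposure] + covariates
        x = _design(df, x_names)
        _check_collinear(x, x_names)
        z = _design(df, ["_iv"] + covariates)
        n, k = len(y), x.shape[1]

        # first stage on the same analysis sample
        fs = first_stage(
            Cohort(data=df, dosage_cols=[], exposure=cohort.exposure,
                   outcomes=[outcome], covariates=covariates),
            df["_iv"],
            covariates,
        )

        # 2SLS: project X onto the instrument space, regress y on the projection
        zb, *_ = np.linalg.lstsq(z, x, rcond=None)
        x_hat = z @ zb
        beta, *_ = np.linalg.lstsq(x_hat, y, rcond=None)
        resid = y - x @ beta  # structural residuals
        xtx_inv = np.linalg.inv(x_hat.T @ x_hat)
        if self.robust:
            meat = x_hat.T @ (x_hat * (resid**2)[:, None])
            cov = xtx_inv @ meat @ xtx_inv
        else:
            sigma2 = float(resid @ resid) / (n - k)
            cov = sigma2 * xtx_inv
        b = float(beta[1])  # exposure coefficient (after intercept)
        se = float(np.sqrt(cov[1, 1]))

        weak = fs.f_stat < self.weak_f_threshold
        if weak:
            warnings.warn(
                f"WEAK INSTRUMENT: first-stage F = {fs.f_stat:.2f} < "
                f"{self.weak_f_threshold:g}; the 2SLS estimate may be badly biased"
            )
        self.beta_ = b
        self.se_ = se
        self.ci_low_ = b - Z95 * se
        self.ci_high_ = b + Z95 * se
        self.pval_ = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else 1.0
        self.first_stage_F_ = fs.f_stat
        self.first_stage_r2_ = fs.r2
        self.n_used_ = n
        self.weak_instrument_ = bool(weak)
        return self

    @property
    def result_(self) -> IVResult:
        return IVResult(
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pval_,
            first_stage_F=self.first_stage_F_,
            first_stage_r2=self.first_stage_r2_,
            n_used=self.n_used_,
            weak_instrument=self.weak_instrument_,
        )


def iv_regression(
    cohort: Cohort,
    outcome: str,
    score: pd.Series,
    covariates: list[str] | None = None,
    *,
    robust: bool = False,
) -> IVResult:
    """2SLS causal estimate of the exposure's effect on ``outcome``."""
    model = TwoStageLeastSquares(robust=robust).fit(cohort, outcome, score, covariates)
    return model.result_


def stratified_iv(
    cohort: Cohort,
    outcome: str,
    score: pd.Series,
    by: str,
    covariates: list[str] | None = None,
    *,
    median_split: bool = False,
) -> dict[str, IVResult]:
    """2SLS within strata of ``by``.

    ``median_split=True`` splits at the median of ``by`` computed on the
    analysis sample, ties (values equal to the median) going to the lower
    stratum; otherwise each distinct value of ``by`` is a stratum.
    The stratifying variable is removed from the within-stratum covariates
    (it is constant inside its own strata).  Degenerate strata (< 30
    complete cases) are skipped with a warning.
    """
    covariates = [c for c in (covariates or []) if c != by]
    values = pd.to_numeric(cohort.data[by], errors="coerce")
    if median_split:
        med = float(values.median())
        labels = np.where(values <= med, f"{by}<= {med:g}", f"{by}> {med:g}")
        labels = pd.Series(labels, index=cohort.data.index).where(values.notna())
    else:
        labels = cohort.data[by].astype(str).where(values.notna() | cohort.data[by].notna())
    results: dict[str, IVResult] = {}
    for label in pd.unique(labels.dropna()):
        mask = labels == label
        sub = Cohort(
            data=cohort.data.loc[mask],
            dosage_cols=cohort.dosage_cols,
            dosage_effect_allele=cohort.dosage_effect_allele,
            exposure=cohort.exposure,
            outcomes=cohort.outcomes,
            covariates=cohort.covariates,
        )
        try:
            results[str(label)] = iv_regression(sub, outcome, score.loc[mask], covariates)
        except ValueError as exc:
            warnings.warn(f"stratum {label!r} skipped: {exc}")
    return results
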
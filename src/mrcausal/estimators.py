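"""Two-sample MR causal estimators over a harmonised instrument set.

Each estimator is a scikit-learn-style class: construct with its tuning
parameters, call ``fit`` on a harmonised instrument table (any DataFrame
with columns ``snp, gamma_hat, sigma_x, Gamma_hat, sigma_y``; rows with a
non-retained ``action`` are ignored), then read the fitted attributes
``beta_, se_, ci_low_, ci_high_, pval_, n_snp_, extras_`` or the bundled
``estimate_``.  Module-level functions (`ivw`, `egger`, `weighted_median`,
`weighted_mode`) are thin wrappers returning an :class:`MREstimate`.

The four methods make complementary pleiotropy assumptions:

* IVW (multiplicative random effects) — all instruments valid, or balanced
  pleiotropy; the precision-weighted mean of per-SNP Wald ratios.
* MR-Egger — directional pleiotropy allowed under InSIDE; weighted
  regression with a free intercept estimating the average direct effect.
* Weighted median — consistent while valid instruments carry >50% of the
  weight.
* Weighted mode — consistent while the largest group of instruments
  sharing a ratio is valid (plurality validity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .summary_data import KEPT_ACTIONS

__all__ = [
    "MREstimate",
    "wald_ratios",
    "instrument_table",
    "BaseMREstimator",
    "IVWEstimator",
    "EggerRegression",
    "WeightedMedianEstimator",
    "WeightedModeEstimator",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One causal estimate: method tag, effect, uncertainty, and extras."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
        }
        d.update({f"extra_{k}": v for k, v in self.extras.items()})
        return d

    def exponentiate(self) -> dict:
        """Odds-ratio view for binary outcomes (betas are log odds ratios)."""
        return {
            "or": float(np.exp(self.beta)),
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
        }


def instrument_table(instruments) -> pd.DataFrame:
    """Validate and normalise an instrument table for estimation.

    Accepts a harmonised DataFrame (non-retained actions filtered out) or
    any frame carrying gamma_hat/sigma_x/Gamma_hat/sigma_y columns.
    """
    df = pd.DataFrame(instruments)
    required = ["gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"instrument table lacks column(s): {', '.join(missing)}")
    if "action" in df.columns:
        df = df.loc[df["action"].isin(KEPT_ACTIONS)]
    if "snp" not in df.columns:
        df = df.assign(snp=[f"snp{i}" for i in range(len(df))])
    df = df.reset_index(drop=True)
    if (df["sigma_x"] <= 0).any() or (df["sigma_y"] <= 0).any():
        raise ValueError("sigma_x and sigma_y must be positive")
    return df


def wald_ratios(instruments) -> pd.DataFrame:
    """Per-SNP Wald ratios: Gamma_hat/gamma_hat with first-order SE sigma_y/|gamma_hat|.

    SNPs with gamma_hat == 0 are excluded with a warning (ratio undefined).
    """
    tab = instrument_table(instruments)
    zero = tab["gamma_hat"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} SNP(s) with zero exposure effect: "
            f"{', '.join(map(str, tab.loc[zero, 'snp']))}"
        )
        tab = tab.loc[~zero].reset_index(drop=True)
    ratio = tab["Gamma_hat"] / tab["gamma_hat"]
    ratio_se = tab["sigma_y"] / tab["gamma_hat"].abs()
    return pd.DataFrame(
        {
            "snp": tab["snp"],
            "ratio": ratio,
            "ratio_se": ratio_se,
            "weight": 1.0 / ratio_se**2,
        }
    )


def _normal_ci_p(beta: float, se: float) -> tuple[float, float, float]:
    ci_low, ci_high = beta - Z95 * se, beta + Z95 * se
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return ci_low, ci_high, max(p, np.finfo(float).tiny)


class BaseMREstimator(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_fit(table)``."""

    method: str = "base"
    min_snps: int = 2

    def fit(self, instruments):
        tab = instrument_table(instruments)
        if len(tab) < self.min_snps:
            raise ValueError(
                f"{self.method} requires at least {self.min_snps} SNPs, got {len(tab)}"
            )
        self.extras_: dict = {}
        self._fit(tab)
        self.n_snp_ = len(tab)
        return self

    def _fit(self, tab: pd.DataFrame) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method=getattr(self, "method_", self.method),
            beta=float(self.beta_),
            se=float(self.se_),
            ci_low=float(self.ci_low_),
            ci_high=float(self.ci_high_),
            pval=float(self.pval_),
            n_snp=int(self.n_snp_),
            extras=dict(self.extras_),
        )


class IVWEstimator(BaseMREstimator):
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Equivalent to the zero-intercept weighted regression of Gamma_hat on
    gamma_hat with weights 1/sigma_y^2.  The multiplicative random-effects
    model inflates the fixed-effect SE by sqrt(max(1, Q/(J-1))) so residual
    heterogeneity widens, and never narrows, the interval.

    A single-SNP input degenerates to the Wald ratio (method tag "wald").
    """

    method = "ivw_mre"
    min_snps = 1

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def _fit(self, tab: pd.DataFrame) -> None:
        wr = wald_ratios(tab)
        r, w = wr["ratio"].to_numpy(), wr["weight"].to_numpy()
        j = len(r)
        beta = float(np.sum(w * r) / np.sum(w))
        fixed_se = float(np.sum(w) ** -0.5)
        if j == 1:
            self.method_ = "wald"
            self.beta_, self.se_ = beta, fixed_se
            self.ci_low_, self.ci_high_, self.pval_ = _normal_ci_p(beta, fixed_se)
            return
        q = float(np.sum(w * (r - beta) ** 2))
        phi = q / (j - 1)
        se = fixed_se * np.sqrt(max(1.0, phi)) if self.random_effects else fixed_se
        self.method_ = self.method
        self.beta_, self.se_ = beta, float(se)
        self.ci_low_, self.ci_high_, self.pval_ = _normal_ci_p(beta, se)
        self.extras_.update({"phi": phi, "Q": q, "fixed_se": fixed_se})


class EggerRegression(BaseMREstimator):
    """MR-Egger: weighted regression of Gamma_hat on gamma_hat with intercept.

    The slope is the causal estimate under InSIDE; the intercept estimates
    the average directional pleiotropic effect.  Instruments must be
    oriented gamma_hat >= 0 (harmonise enforces this).  Inference uses the
    t distribution with J-2 degrees of freedom; both SEs carry the
    multiplicative overdispersion inflation sqrt(max(1, RSS_w/(J-2))).
    """

    method = "egger"
    min_snps = 3

    def _fit(self, tab: pd.DataFrame) -> None:
        x = tab["gamma_hat"].to_numpy(float)
        y = tab["Gamma_hat"].to_numpy(float)
        w = 1.0 / tab["sigma_y"].to_numpy(float) ** 2
        j = len(x)
        if np.allclose(x, x[0]):
            raise ValueError("all gamma_hat identical: Egger design is rank deficient")
        sw, swx = w.sum(), (w * x).sum()
        swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
        det = sw * swxx - swx**2
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        resid = y - intercept - slope * x
        rss_w = float(np.sum(w * resid**2))
        phi = rss_w / (j - 2)
        infl = np.sqrt(max(1.0, phi))
        slope_se = np.sqrt(sw / det) * infl
        intercept_se = np.sqrt(swxx / det) * infl
        tdist = stats.t(j - 2)
        self.beta_, self.se_ = float(slope), float(slope_se)
        tcrit = tdist.ppf(0.975)
        self.ci_low_ = float(slope - tcrit * slope_se)
        self.ci_high_ = float(slope + tcrit * slope_se)
        self.pval_ = float(2 * tdist.sf(abs(slope) / slope_se))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(intercept_se)
        self.intercept_pval_ = float(2 * tdist.sf(abs(intercept) / intercept_se))
        self.extras_.update(
            {
                "intercept": self.intercept_,
                "intercept_se": self.intercept_se_,
                "intercept_pval": self.intercept_pval_,
                "phi": phi,
            }
        )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median via cumulative-midpoint positions."""
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5))
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


class _BootstrapMixin:
    """Parametric bootstrap over (gamma_hat, Gamma_hat) for median/mode SEs."""

    def _bootstrap_draws(self, tab: pd.DataFrame, rng: np.random.Generator):
        g = tab["gamma_hat"].to_numpy(float)
        G = tab["Gamma_hat"].to_numpy(float)
        sx = tab["sigma_x"].to_numpy(float)
        sy = tab["sigma_y"].to_numpy(float)
        b = self.n_boot
        g_star = g + sx * rng.standard_normal((b, len(g)))
        G_star = G + sy * rng.standard_normal((b, len(g)))
        g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
        ratios = G_star / g_star
        weights = (g_star / sy) ** 2
        return ratios, weights


class WeightedMedianEstimator(BaseMREstimator, _BootstrapMixin):
    """Weighted median of Wald ratios; valid while >50% of weight is valid.

    SE from a parametric bootstrap: gamma_hat and Gamma_hat are redrawn
    from normal(observed, se), the weighted median recomputed, and the
    standard deviation over ``n_boot`` draws taken under a fixed seed.
    """

    method = "weighted_median"
    min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, tab: pd.DataFrame) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for the bootstrap (no silent global RNG)")
        wr = wald_ratios(tab)
        beta = weighted_median_point(wr["ratio"].to_numpy(), wr["weight"].to_numpy())
        rng = np.random.default_rng(self.seed)
        ratios, weights = self._bootstrap_draws(tab, rng)
        boot = np.array(
            [weighted_median_point(ratios[b], weights[b]) for b in range(self.n_boot)]
        )
        se = float(boot.std(ddof=1))
        self.beta_, self.se_ = float(beta), se
        self.ci_low_, self.ci_high_, self.pval_ = _normal_ci_p(beta, se)
        self.extras_.update({"n_boot": self.n_boot})


def _mode_bandwidth(ratios: np.ndarray, multiplier: float) -> float:
    """Silverman-style rule of thumb: 0.9 * min(sd, MAD/0.6745) * J^(-1/5)."""
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return 0.0
    return multiplier * 0.9 * min(candidates) * j ** (-1 / 5)


def _kde_argmax(ratios: np.ndarray, weights: np.ndarray, h: float, grid_size: int = 512,
                refine: bool = True) -> float:
    """Maximiser of the weighted Gaussian KDE over the ratios."""
    w = weights / weights.sum()
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    if not refine:
        return float(grid[i])
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]

    def neg_density(x):
        return -(w * np.exp(-0.5 * ((x - ratios) / h) ** 2)).sum()

    res = optimize.minimize_scalar(
        neg_density, bounds=(a, b), method="bounded",
        options={"xatol": 1e-10 * (hi - lo)},
    )
    return float(res.x)


class WeightedModeEstimator(BaseMREstimator, _BootstrapMixin):
    """Weighted mode of Wald ratios (plurality-valid assumption).

    The estimate maximises a weighted Gaussian kernel density over the
    ratios, with a Silverman-style bandwidth scaled by
    ``bandwidth_multiplier``; the maximiser is located on a fine grid and
    refined by bounded optimisation.  SE by the same parametric bootstrap
    as the weighted median (bandwidth recomputed per draw; grid-only
    maximisation inside the bootstrap).
    """

    method = "weighted_mode"
    min_snps = 3

    def __init__(
        self,
        bandwidth_multiplier: float = 1.0,
        n_boot: int = 1000,
        seed: int | None = None,
        grid_size: int = 512,
        boot_grid_size: int = 256,
    ):
        self.bandwidth_multiplier = bandwidth_multiplier
        self.n_boot = n_boot
        self.seed = seed
        self.grid_size = grid_size
        self.boot_grid_size = boot_grid_size

    def _fit(self, tab: pd.DataFrame) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for the bootstrap (no silent global RNG)")
        wr = wald_ratios(tab)
        r, w = wr["ratio"].to_numpy(), wr["weight"].to_numpy()
        h = _mode_bandwidth(r, self.bandwidth_multiplier)
        rng = np.random.default_rng(self.seed)
        if h == 0.0:
            # degenerate: every ratio identical
            beta = float(r[0])
            ratios, weights = self._bootstrap_draws(tab, rng)
            boot = np.array(
                [self._boot_point(ratios[b], weights[b]) for b in range(self.n_boot)]
            )
            se = float(boot.std(ddof=1))
        else:
            beta = _kde_argmax(r, w, h, self.grid_size)
            ratios, weights = self._bootstrap_draws(tab, rng)
            boot = np.array(
                [self._boot_point(ratios[b], weights[b]) for b in range(self.n_boot)]
            )
            se = float(boot.std(ddof=1))
        self.beta_, self.se_ = beta, se
        self.ci_low_, self.ci_high_, self.pval_ = _normal_ci_p(beta, se)
        self.extras_.update(
            {"bandwidth": h, "bandwidth_multiplier": self.bandwidth_multiplier,
             "n_boot": self.n_boot}
        )

    def _boot_point(self, ratios: np.ndarray, weights: np.ndarray) -> float:
        h = _mode_bandwidth(ratios, self.bandwidth_multiplier)
        if h == 0.0:
            return float(ratios[0])
        return _kde_argmax(ratios, weights, h, self.boot_grid_size, refine=False)


def ivw(instruments, **kwargs) -> MREstimate:
    """Inverse-variance-weighted (multiplicative random effects) estimate."""
    return IVWEstimator(**kwargs).fit(instruments).estimate_


def egger(instruments) -> MREstimate:
    """MR-Egger slope (+ intercept in extras)."""
    return EggerRegression().fit(instruments).estimate_


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(instruments).estimate_


def weighted_mode(
    instruments,
    bandwidth_multiplier: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    return (
        WeightedModeEstimator(bandwidth_multiplier=bandwidth_multiplier, n_boot=n_boot, seed=seed)
        .fit(instruments)
        .estimate_
    )
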
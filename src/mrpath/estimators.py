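"""Univariable two-sample MR causal-effect estimators.

All estimators consume a :class:`~mrpath.instruments.HarmonizedSet` and
return an :class:`MREstimate` on the log-odds (beta) scale together with
its odds-ratio transform. Five methods are provided:

* inverse-variance weighted (IVW), fixed- or multiplicative-random-effects;
* MR-Egger regression (slope = causal effect, intercept = directional
  pleiotropy);
* weighted median of the per-SNP Wald ratios;
* simple and weighted mode-based estimators (kernel density argmax).

A primary-estimate selection rule mirrors common reporting practice:
MR-Egger when the intercept test indicates pleiotropy, random-effects IVW
under significant heterogeneity, fixed-effects IVW otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientInstrumentsError
from .instruments import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96

WALD_RATIO = "wald_ratio"
IVW_FIXED = "ivw_fixed"
IVW_RANDOM = "ivw_random"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
SIMPLE_MODE = "simple_mode"
WEIGHTED_MODE = "weighted_mode"


@dataclass(frozen=True)
class EggerIntercept:
    value: float
    se: float
    pval: float


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate with its odds-scale transform."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    egger_intercept: EggerIntercept | None = None


def to_odds_scale(beta: float, se: float) -> dict:
    """Odds ratio and 95% CI from a log-odds effect and its SE."""
    return {
        "or_": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - Z95 * se)),
        "ci_high": float(np.exp(beta + Z95 * se)),
    }


def _estimate(method, nsnp, beta, se, pval, intercept=None) -> MREstimate:
    odds = to_odds_scale(beta, se)
    return MREstimate(
        method=method,
        nsnp=int(nsnp),
        beta=float(beta),
        se=float(se),
        pval=float(pval),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        or_=odds["or_"],
        or_ci_low=odds["ci_low"],
        or_ci_high=odds["ci_high"],
        egger_intercept=intercept,
    )


def _kept_arrays(h: HarmonizedSet):
    k = h.kept
    return (
        k["snp"].to_numpy(),
        k["beta_exp"].to_numpy(float),
        k["se_exp"].to_numpy(float),
        k["beta_out"].to_numpy(float),
        k["se_out"].to_numpy(float),
    )


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_out/beta_exp with delta-method SEs.

    The default SE is the first-order approximation se_out/|beta_exp|
    (outcome noise only); ``second_order`` adds the exposure-noise term.
    SNPs with beta_exp == 0 are excluded with a warning.
    """
    snp, bx, sx, by, sy = _kept_arrays(h)
    nonzero = bx != 0
    if not nonzero.all():
        logger.warning(
            "excluding %d SNPs with zero exposure effect from Wald ratios",
            int((~nonzero).sum()),
        )
    snp, bx, sx, by, sy = (a[nonzero] for a in (snp, bx, sx, by, sy))
    ratio = by / bx
    se = sy / np.abs(bx)
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return pd.DataFrame({"snp": snp, "ratio": ratio, "se": se})


def ivw(h: HarmonizedSet, mode: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Zero-intercept regression of outcome on exposure betas with weights
    1/se_out²: beta = Σ(w·bx·by)/Σ(w·bx²). Fixed mode keeps the residual
    scale at 1; random mode (multiplicative random effects) inflates the
    SE by sqrt(max(1, Q/df)). p-values are normal-based.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be fixed|random")
    _, bx, _, by, sy = _kept_arrays(h)
    n = len(bx)
    if n < 2:
        raise InsufficientInstrumentsError(2, n, "use a single-SNP Wald ratio")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se = np.sqrt(1.0 / sxx)
    if mode == "random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= np.sqrt(max(1.0, q / (n - 1)))
    pval = 2 * stats.norm.sf(abs(beta) / se)
    return _estimate(IVW_FIXED if mode == "fixed" else IVW_RANDOM, n, beta, se, pval)


def mr_egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit with a free intercept.

    SNPs are oriented so beta_exp ≥ 0 first. The slope is the causal
    estimate; the intercept (with its t-based test, df = nsnp − 2)
    measures directional pleiotropy. The residual scale is bounded below
    by 1 (multiplicative random effects).
    """
    _, bx, _, by, sy = _kept_arrays(h)
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(3, n)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # (X'WX)^{-1} with the residual scale floored at 1 (multiplicative
    # random effects); avoids 0/0 on exact-fit data where fit.scale == 0
    bse = np.sqrt(max(1.0, fit.scale) * np.diag(fit.normalized_cov_params))
    df = n - 2
    intercept_p = 2 * stats.t.sf(abs(fit.params[0] / bse[0]), df)
    slope_p = 2 * stats.t.sf(abs(fit.params[1] / bse[1]), df)
    intercept = EggerIntercept(float(fit.params[0]), float(bse[0]), float(intercept_p))
    return _estimate(EGGER, n, fit.params[1], bse[1], slope_p, intercept)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile by linear interpolation across the midpoint
    cumulative normalized weights."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios (weights 1/se_ratio²).

    Consistent when instruments carrying ≥50% of the weight are valid.
    The SE comes from a seeded parametric bootstrap: ratios are perturbed
    by their SEs and the weighted median recomputed ``n_boot`` times.
    """
    wr = wald_ratios(h)
    n = len(wr)
    if n < 3:
        raise InsufficientInstrumentsError(3, n)
    ratios = wr["ratio"].to_numpy()
    ses = wr["se"].to_numpy()
    weights = 1.0 / ses**2
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(rng.normal(ratios, ses), weights)
    se = float(np.std(boots, ddof=1))
    pval = 2 * stats.norm.sf(abs(beta) / se)
    return _estimate(WEIGHTED_MEDIAN, n, beta, se, pval)


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9·min(sd, mad)·n^(−1/5), scaled by factor."""
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad) * len(ratios) ** (-0.2)
    return max(1e-8, s * factor)


def _kde_argmax(ratios, weights, bandwidth, grid_size=4097) -> float:
    """Argmax of the weighted normal-kernel density on a fixed grid.

    The grid spans the ratio range extended by 3 bandwidths; resolution is
    deterministic so the estimate is exactly reproducible.
    """
    lo = ratios.min() - 3 * bandwidth
    hi = ratios.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - ratios[None, :]) / bandwidth
    dens = (np.exp(-0.5 * z**2) * weights[None, :]).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_size: int = 4097,
) -> MREstimate:
    """Mode-based estimate: the argmax of a kernel density over Wald ratios.

    ``weighted`` uses 1/se² kernel weights (weighted mode); otherwise all
    ratios weigh equally (simple mode). Bandwidth is ``bandwidth_factor``
    times the modified Silverman rule. SE by seeded parametric bootstrap.
    Consistent when the largest cluster of instruments is valid (ZEMPA).
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    wr = wald_ratios(h)
    n = len(wr)
    if n < 3:
        raise InsufficientInstrumentsError(3, n)
    ratios = wr["ratio"].to_numpy()
    ses = wr["se"].to_numpy()
    weights = 1.0 / ses**2 if weighted else np.ones(n)
    weights = weights / weights.sum()

    if np.ptp(ratios) == 0:  # degenerate: all ratios identical
        beta = float(ratios[0])
    else:
        beta = _kde_argmax(ratios, weights, _mode_bandwidth(ratios, bandwidth_factor),
                           grid_size)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r = rng.normal(ratios, ses)
        boots[b] = (
            float(np.median(r))
            if np.ptp(r) == 0
            else _kde_argmax(r, weights, _mode_bandwidth(r, bandwidth_factor),
                             grid_size)
        )
    se = float(np.std(boots, ddof=1))
    pval = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return _estimate(WEIGHTED_MODE if weighted else SIMPLE_MODE, n, beta, se, pval)


def all_estimates(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> dict[str, MREstimate]:
    """The five standard estimates (plus both IVW variants) for one pair."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    return {
        IVW_FIXED: ivw(h, "fixed"),
        IVW_RANDOM: ivw(h, "random"),
        EGGER: mr_egger(h),
        WEIGHTED_MEDIAN: weighted_median(h, n_boot, int(seeds[0])),
        SIMPLE_MODE: mode_estimate(h, False, 1.0, n_boot, int(seeds[1])),
        WEIGHTED_MODE: mode_estimate(h, True, 1.0, n_boot, int(seeds[2])),
    }


def select_primary(estimates: dict, het, pleio) -> MREstimate:
    """Primary-estimate rule: Egger under pleiotropy (intercept p < 0.05),
    random-effects IVW under heterogeneity (Q p < 0.05), else fixed IVW."""
    if pleio.pval < 0.05:
        return estimates[EGGER]
    if het.pval < 0.05:
        return estimates[IVW_RANDOM]
    return estimates[IVW_FIXED]
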
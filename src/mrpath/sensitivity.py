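"""Heterogeneity, pleiotropy, leave-one-out, funnel and directionality
diagnostics for a harmonized instrument set.

Cochran's Q measures dispersion of the per-SNP Wald ratios about the
pooled estimate; I² = max(0, (Q − df)/Q) × 100 expresses it as the share
of variation beyond sampling noise, banded none / mild (0–25] /
moderate (25–50] / high (>50). The MR-Egger intercept tests directional
pleiotropy. Leave-one-out flags single influential instruments. The
Steiger test compares instrument-explained variance in exposure versus
outcome to check that causality runs in the assumed direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError, MissingSampleSizeError
from .estimators import MREstimate, ivw, mr_egger, wald_ratios
from .instruments import HarmonizedSet

BAND_NONE = "none"
BAND_MILD = "mild"
BAND_MODERATE = "moderate"
BAND_HIGH = "high"


@dataclass(frozen=True)
class HeterogeneityReport:
    Q: float
    df: int
    pval: float
    i2: float
    band: str


@dataclass(frozen=True)
class PleiotropyTest:
    intercept: float
    se: float
    pval: float
    pleiotropic: bool


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    indeterminate: bool
    pval: float


def i2_band(i2: float) -> str:
    """Qualitative band for an I² percentage (boundaries closed on the
    right: 25 is mild, 50 is moderate)."""
    if i2 <= 0:
        return BAND_NONE
    if i2 <= 25:
        return BAND_MILD
    if i2 <= 50:
        return BAND_MODERATE
    return BAND_HIGH


def heterogeneity_from_q(q: float, df: int) -> HeterogeneityReport:
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    return HeterogeneityReport(float(q), int(df), pval, float(i2), i2_band(i2))


def cochran_q(
    h: HarmonizedSet,
    model_beta: float | None = None,
    about: str = "ivw",
) -> HeterogeneityReport:
    """Cochran's Q about a pooled estimate.

    Q = Σ w_j (ratio_j − beta)², w_j = 1/se_ratio_j². By default the
    pooled beta is the fixed-effects IVW estimate (df = nsnp − 1); with
    ``about="egger"`` residuals are taken about the Egger fit
    (df = nsnp − 2). ``model_beta`` overrides the pooled estimate but
    keeps the IVW df convention.
    """
    if about not in ("ivw", "egger"):
        raise ValueError("about must be ivw|egger")
    wr = wald_ratios(h)
    n = len(wr)
    if n < 2:
        raise InsufficientInstrumentsError(2, n)
    ratios = wr["ratio"].to_numpy()
    w = 1.0 / wr["se"].to_numpy() ** 2
    if about == "egger":
        est = mr_egger(h)
        k = h.kept
        bx = np.abs(k["beta_exp"].to_numpy(float))  # Egger orientation
        by = k["beta_out"].to_numpy(float) * np.sign(k["beta_exp"].to_numpy(float))
        resid = by - est.egger_intercept.value - est.beta * bx
        q = float(np.sum(resid**2 / k["se_out"].to_numpy(float) ** 2))
        return heterogeneity_from_q(q, n - 2)
    beta = ivw(h, "fixed").beta if model_beta is None else model_beta
    q = float(np.sum(w * (ratios - beta) ** 2))
    return heterogeneity_from_q(q, n - 1)


def egger_intercept_test(egger: MREstimate) -> PleiotropyTest:
    """Directional-pleiotropy test from the stored MR-Egger intercept
    (t-based, df = nsnp − 2, significant strictly below 0.05)."""
    ic = egger.egger_intercept
    if ic is None:
        raise ValueError("estimate carries no Egger intercept")
    return PleiotropyTest(ic.value, ic.se, ic.pval, bool(ic.pval < 0.05))


def leave_one_out(h: HarmonizedSet, mode: str = "fixed") -> pd.DataFrame:
    """IVW re-estimated excluding each kept SNP in turn.

    A SNP is flagged when its exclusion flips the sign of the estimate or
    moves it outside the full-set 95% CI.
    """
    kept = h.kept
    n = len(kept)
    if n < 3:
        raise InsufficientInstrumentsError(3, n)
    full = ivw(h, mode)
    rows = []
    for snp in kept["snp"]:
        sub = h.drop_snps([snp])
        est = ivw(sub, mode)
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or not (
            full.ci_low <= est.beta <= full.ci_high
        )
        rows.append(
            {
                "snp": snp,
                "nsnp": est.nsnp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Plot-ready funnel table: per-SNP Wald ratio and precision 1/se."""
    wr = wald_ratios(h)
    if len(wr) < 2:
        raise InsufficientInstrumentsError(2, len(wr))
    return pd.DataFrame(
        {"snp": wr["snp"], "ratio": wr["ratio"], "precision": 1.0 / wr["se"]}
    )


def _r2_from_t(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> float:
    """Instrument-set variance explained via the t-statistic transform
    r²_j = t²/(t² + n − 2), summed over instruments."""
    t2 = (beta / se) ** 2
    return float(np.sum(t2 / (t2 + n - 2)))


def _r2_from_eaf(beta: np.ndarray, eaf: np.ndarray) -> float:
    return float(np.sum(2 * eaf * (1 - eaf) * beta**2))


def steiger(h: HarmonizedSet, use_eaf: bool = False) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    The two explained-variance estimates are compared through Fisher's
    z-transform of the corresponding multiple correlations, with a
    two-sample z-test using the harmonic-style 1/(n−3) variances.
    """
    k = h.kept
    for trait, col in ((h.exposure_id, "n_exp"), (h.outcome_id, "n_out")):
        if k[col].isna().any():
            raise MissingSampleSizeError(trait)
    n_exp = k["n_exp"].to_numpy(float)
    n_out = k["n_out"].to_numpy(float)
    if use_eaf:
        if k["eaf_exp"].isna().any() or k["eaf_out"].isna().any():
            raise MissingSampleSizeError("eaf-based r2 requires eaf on both traits")
        r2_exp = _r2_from_eaf(k["beta_exp"].to_numpy(float), k["eaf_exp"].to_numpy(float))
        r2_out = _r2_from_eaf(k["beta_out"].to_numpy(float), k["eaf_out"].to_numpy(float))
    else:
        r2_exp = _r2_from_t(
            k["beta_exp"].to_numpy(float), k["se_exp"].to_numpy(float), n_exp
        )
        r2_out = _r2_from_t(
            k["beta_out"].to_numpy(float), k["se_out"].to_numpy(float), n_out
        )
    r2_exp = min(r2_exp, 1.0)
    r2_out = min(r2_out, 1.0)
    z_exp = np.arctanh(min(np.sqrt(r2_exp), 1 - 1e-12))
    z_out = np.arctanh(min(np.sqrt(r2_out), 1 - 1e-12))
    denom = np.sqrt(1.0 / (np.mean(n_exp) - 3) + 1.0 / (np.mean(n_out) - 3))
    z = (z_exp - z_out) / denom
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=bool(r2_exp > r2_out),
        indeterminate=bool(pval > 0.05),
        pval=pval,
    )
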
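"""Product-of-coefficients mediation on MR effect estimates.

The indirect (mediated) path exposure → mediator → outcome is quantified
as β_M = β_A · β_B, where β_A is the univariable MR effect of the
exposure on the mediator and β_B the mediator's direct effect on the
outcome from multivariable MR. The SE uses the Aroian variant of the
product-of-coefficients formula,

    SE_M = sqrt(β_A²·SE_B² + β_B²·SE_A² + SE_A²·SE_B²),

whose exact third term makes it an unbiased variance for the product of
two independent normals. Mediation is classified complete (both path
legs significant, direct effect not) or partial (all three significant);
the proportion mediated divides |β_M| by the direct effect when the two
have opposite signs and by the total effect otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

Z95 = 1.96

COMPLETE = "complete"
PARTIAL = "partial"
NONE = "none"

DENOM_DIRECT = "direct"
DENOM_TOTAL = "total"


def _z_pval(beta: float, se: float) -> float:
    if se <= 0:
        return 1.0
    return 2 * stats.norm.sf(abs(beta) / se)


@dataclass(frozen=True)
class MediationInput:
    """The four MR effects feeding one mediation model.

    A: exposure→mediator (univariable MR); B: mediator→outcome direct
    effect (MVMR); C: exposure→outcome total effect (univariable MR);
    C′: exposure→outcome direct effect (MVMR). p-values default to the
    normal z-test of each beta against its SE.
    """

    beta_A: float
    se_A: float
    beta_B: float
    se_B: float
    beta_C: float
    se_C: float
    beta_Cprime: float
    se_Cprime: float
    p_A: float | None = None
    p_B: float | None = None
    p_Cprime: float | None = None

    def __post_init__(self) -> None:
        for name in ("se_A", "se_B", "se_C", "se_Cprime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def pval_A(self) -> float:
        return self.p_A if self.p_A is not None else _z_pval(self.beta_A, self.se_A)

    @property
    def pval_B(self) -> float:
        return self.p_B if self.p_B is not None else _z_pval(self.beta_B, self.se_B)

    @property
    def pval_Cprime(self) -> float:
        return (
            self.p_Cprime
            if self.p_Cprime is not None
            else _z_pval(self.beta_Cprime, self.se_Cprime)
        )


@dataclass
class MediationResult:
    beta_M: float
    se_M: float
    ci_low: float
    ci_high: float
    mediation_class: str | None = None
    proportion: float | None = None
    denominator_used: str | None = None


def aroian_se(beta_A: float, se_A: float, beta_B: float, se_B: float) -> float:
    """Aroian product-of-coefficients SE."""
    return math.sqrt(
        beta_A**2 * se_B**2 + beta_B**2 * se_A**2 + se_A**2 * se_B**2
    )


def mediation_effect(inp: MediationInput) -> MediationResult:
    """β_M = β_A·β_B with Aroian SE and normal 95% CI."""
    beta_m = inp.beta_A * inp.beta_B
    se_m = aroian_se(inp.beta_A, inp.se_A, inp.beta_B, inp.se_B)
    return MediationResult(
        beta_M=beta_m,
        se_M=se_m,
        ci_low=beta_m - Z95 * se_m,
        ci_high=beta_m + Z95 * se_m,
    )


def classify_mediation(inp: MediationInput, alpha: float = 0.05) -> str:
    """complete / partial / none.

    The mediated path is established when both legs (A and B) are
    significant; the direct effect then separates complete (p_C′ ≥ alpha)
    from partial (p_C′ < alpha) mediation.
    """
    path_significant = inp.pval_A < alpha and inp.pval_B < alpha
    if not path_significant:
        return NONE
    return PARTIAL if inp.pval_Cprime < alpha else COMPLETE


def proportion_mediated(
    inp: MediationInput, res: MediationResult
) -> tuple[float | None, str | None]:
    """Percentage of the effect carried by the mediated path.

    When β_M and the direct effect β_C′ have opposite signs the two paths
    counteract and the proportion is taken against the direct effect,
    |β_M/β_C′|·100; with concordant signs it is taken against the total
    effect, |β_M/β_C|·100. Returns (percentage, denominator) or
    (None, None) when the denominator is zero.
    """
    beta_m = res.beta_M
    opposite = (beta_m >= 0) != (inp.beta_Cprime >= 0)
    denom = inp.beta_Cprime if opposite else inp.beta_C
    label = DENOM_DIRECT if opposite else DENOM_TOTAL
    if denom == 0:
        return None, None
    return abs(beta_m / denom) * 100.0, label


def run_mediation(inp: MediationInput, alpha: float = 0.05) -> MediationResult:
    """Full mediation summary: effect, CI, class and proportion."""
    res = mediation_effect(inp)
    res.mediation_class = classify_mediation(inp, alpha)
    res.proportion, res.denominator_used = proportion_mediated(inp, res)
    return res
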
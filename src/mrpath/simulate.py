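"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator works directly at the summary level: for each independent
biallelic instrument it draws a minor-allele frequency, a true per-allele
effect, and observed effects equal to truth plus Gaussian sampling noise
with the analytic GWAS standard error 1/sqrt(2·maf·(1−maf)·n). The three
traits' noise draws are independent, matching the two-sample assumption
of non-overlapping cohorts.

The causal structure is the mediation chain

    exposure  --beta_A-->  mediator  --beta_B-->  outcome
        \\_________________beta_direct________________/

Exposure instruments carry effects gamma_j on the exposure (jointly
explaining ``variance_share`` of its variance), beta_A·gamma_j on the
mediator and (beta_direct + beta_A·beta_B)·gamma_j on the outcome.
Mediator-specific instruments (``m_med_snps``) affect only the mediator
and, through it, the outcome — without them the mediator's direct effect
would be unidentifiable in a multivariable design built from this chain.
Outcome-specific instruments (``m_out_snps``, off by default) give the
outcome its own genetic signal, e.g. for reverse-direction analyses.
Optional horizontal pleiotropy adds per-SNP effects directly on the
outcome (balanced: mean 0; directional: nonzero mean), and ``het_sd``
adds extra outcome-effect dispersion to dial in heterogeneity.

Effect alleles are coded as the trait-increasing allele of the underlying
causal chain (all gamma_j > 0); each trait's emitted records are
randomly strand/orientation-shuffled, including occasional palindromic
allele pairs, to exercise harmonization downstream.

Defaults mirror the study conditions this package targets: instrument
counts (200 for an anthropometric exposure, 30 for a metabolite) and GWAS
sample sizes (330k / 115k / 218k) follow the source cohorts, and the
instrument panels are strong (variance share 0.20, mean per-SNP F of
several hundred), as appropriate for post-selection genome-wide
significant loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateConfigError
from .mediation import MediationInput
from .sumstats import SummaryStats
from scipy import stats

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal pleiotropy acting directly on the outcome."""

    mode: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy mode must be none|balanced|directional")


@dataclass(frozen=True)
class SimConfig:
    m_snps: int = 200
    m_med_snps: int = 30
    m_out_snps: int = 0
    n_exp: int = 330_000
    n_med: int = 115_000
    n_out: int = 218_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_A: float = 0.3
    beta_B: float = 0.2
    beta_direct: float = 0.1
    variance_share: float = 0.2
    variance_share_med: float = 0.2
    variance_share_out: float = 0.05
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    het_sd: float = 0.0
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise DegenerateConfigError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DegenerateConfigError("maf_range must be within (0, 0.5]")
        if not 0 < self.variance_share < 1:
            raise DegenerateConfigError("variance_share must be in (0, 1)")
        if self.m_med_snps > 0 and not 0 < self.variance_share_med < 1:
            raise DegenerateConfigError("variance_share_med must be in (0, 1)")
        if self.m_out_snps > 0 and not 0 < self.variance_share_out < 1:
            raise DegenerateConfigError("variance_share_out must be in (0, 1)")
        if self.m_snps < 1:
            raise DegenerateConfigError("m_snps must be >= 1")


@dataclass
class SimTruth:
    """Per-SNP true effects and the implied path arithmetic."""

    snp: np.ndarray
    gamma_exposure: np.ndarray
    effect_mediator: np.ndarray
    effect_outcome: np.ndarray
    pleiotropy: np.ndarray
    true_direct: float
    true_mediation: float

    @property
    def true_total(self) -> float:
        return self.true_direct + self.true_mediation


@dataclass
class SimResult:
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    truth: SimTruth
    config: SimConfig


def _emit_trait(
    rng: np.random.Generator,
    trait_id: str,
    snps: np.ndarray,
    alleles: list[tuple[str, str]],
    maf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
) -> SummaryStats:
    """Observed summary table: truth + noise, randomly re-oriented records."""
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    beta = rng.normal(true_beta, se)
    swap = rng.random(len(snps)) < 0.5
    ea = np.array([a[0] for a in alleles])
    oa = np.array([a[1] for a in alleles])
    ea_out = np.where(swap, oa, ea)
    oa_out = np.where(swap, ea, oa)
    beta_out = np.where(swap, -beta, beta)
    eaf_out = np.where(swap, 1 - maf, maf)
    pval = 2 * stats.norm.sf(np.abs(beta_out / se))
    df = pd.DataFrame(
        {
            "snp": snps,
            "effect_allele": ea_out,
            "other_allele": oa_out,
            "eaf": eaf_out,
            "beta": beta_out,
            "se": se,
            "pval": np.clip(pval, np.finfo(float).tiny, 1.0),
            "n": float(n),
        }
    )
    return SummaryStats(trait_id, df)


def simulate_sumstats(cfg: SimConfig) -> SimResult:
    """Draw one synthetic exposure/mediator/outcome summary-statistics set.

    Deterministic in ``cfg.seed``: the same config yields bit-identical
    tables.
    """
    rng = np.random.default_rng(cfg.seed)
    m, mm, mo = cfg.m_snps, cfg.m_med_snps, cfg.m_out_snps
    total = m + mm + mo
    snps = np.array([f"rs{j + 1}" for j in range(total)])
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=total)
    var_allele = 2 * maf * (1 - maf)

    def _panel_effects(sl: slice, share: float) -> np.ndarray:
        # per-SNP explained-variance contributions follow a shifted
        # exponential (mean 1, floor 0.25, normalized to the panel share).
        # Heterogeneous strengths mirror real GWAS effect-size
        # distributions (near-equal strengths leave Egger-type regressions
        # without x-spread); the floor mirrors the fact that an instrument
        # panel consists of loci that already cleared genome-wide
        # significance, so no "instrument" sits below the selection
        # threshold it was defined by
        count = sl.stop - sl.start
        shares = 0.25 + rng.exponential(0.75, size=count)
        shares *= share / shares.sum()
        return np.sqrt(shares / var_allele[sl])

    gamma = np.zeros(total)
    gamma[:m] = _panel_effects(slice(0, m), cfg.variance_share)
    gamma_med = np.zeros(total)
    if mm:
        gamma_med[m : m + mm] = _panel_effects(
            slice(m, m + mm), cfg.variance_share_med
        )
    gamma_out = np.zeros(total)
    if mo:
        gamma_out[m + mm :] = _panel_effects(
            slice(m + mm, total), cfg.variance_share_out
        )

    pleio = np.zeros(total)
    if cfg.pleiotropy.mode == "balanced":
        pleio = rng.normal(0.0, cfg.pleiotropy.sd, size=total)
    elif cfg.pleiotropy.mode == "directional":
        pleio = rng.normal(cfg.pleiotropy.mean, cfg.pleiotropy.sd, size=total)

    het = rng.normal(0.0, cfg.het_sd, size=total) if cfg.het_sd > 0 else np.zeros(total)

    effect_exp = gamma
    effect_med = cfg.beta_A * gamma + gamma_med
    effect_out = (
        (cfg.beta_direct + cfg.beta_A * cfg.beta_B) * gamma
        + cfg.beta_B * gamma_med
        + gamma_out
        + pleio
        + het
    )

    n_pal = int(round(cfg.palindromic_fraction * total))
    is_pal = np.zeros(total, dtype=bool)
    if n_pal:
        is_pal[rng.choice(total, size=n_pal, replace=False)] = True
    alleles = [
        PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
        if is_pal[j]
        else NONPALINDROMIC_PAIRS[rng.integers(len(NONPALINDROMIC_PAIRS))]
        for j in range(total)
    ]

    exposure = _emit_trait(rng, "sim_exposure", snps, alleles, maf, effect_exp, cfg.n_exp)
    mediator = _emit_trait(rng, "sim_mediator", snps, alleles, maf, effect_med, cfg.n_med)
    outcome = _emit_trait(rng, "sim_outcome", snps, alleles, maf, effect_out, cfg.n_out)

    truth = SimTruth(
        snp=snps,
        gamma_exposure=effect_exp,
        effect_mediator=effect_med,
        effect_outcome=effect_out,
        pleiotropy=pleio,
        true_direct=cfg.beta_direct,
        true_mediation=cfg.beta_A * cfg.beta_B,
    )
    return SimResult(exposure, mediator, outcome, truth, cfg)


@dataclass(frozen=True)
class PrintedMediationRow:
    """One published mediation model: effects with 95% CIs as printed."""

    exposure: str
    mediator: str
    outcome: str
    total: tuple[float, float, float]  # beta_C (lo, hi)
    effect_em: tuple[float, float, float]  # beta_A
    effect_mo: tuple[float, float, float]  # beta_B
    effect_eo: tuple[float, float, float]  # beta_C' (direct)
    mediation: tuple[float, float, float]  # beta_M as printed

    @staticmethod
    def _se(ci: tuple[float, float, float]) -> float:
        _, lo, hi = ci
        return (hi - lo) / 3.92

    def as_input(self) -> MediationInput:
        return MediationInput(
            beta_A=self.effect_em[0],
            se_A=self._se(self.effect_em),
            beta_B=self.effect_mo[0],
            se_B=self._se(self.effect_mo),
            beta_C=self.total[0],
            se_C=self._se(self.total),
            beta_Cprime=self.effect_eo[0],
            se_Cprime=self._se(self.effect_eo),
        )


def fixture_tables() -> list[PrintedMediationRow]:
    """The four published mediation models (two complete, two partial),
    transcribed with their printed effects and 95% CIs."""
    ad = "anxiety disorder"
    return [
        PrintedMediationRow(
            "body fat percentage", "phenylalanine", ad,
            (0.133, 0.011, 0.255),
            (0.168, 0.123, 0.213),
            (0.166, 0.005, 0.327),
            (0.076, -0.046, 0.198),
            (0.028, 0.0, 0.056),
        ),
        PrintedMediationRow(
            "body fat percentage",
            "free cholesterol to total-lipids ratio in very small VLDL", ad,
            (0.133, 0.011, 0.255),
            (-0.155, -0.224, -0.086),
            (-0.088, -0.168, -0.008),
            (0.099, -0.028, 0.226),
            (0.014, 0.0, 0.028),
        ),
        PrintedMediationRow(
            "body fat percentage",
            "ratio of linoleic acid to total fatty acids", ad,
            (0.133, 0.011, 0.255),
            (-0.392, -0.472, -0.312),
            (0.108, 0.012, 0.204),
            (0.168, 0.041, 0.295),
            (-0.042, -0.081, -0.003),
        ),
        PrintedMediationRow(
            "obesity and other hyperalimentation", "phenylalanine", ad,
            (-0.103, -0.189, -0.017),
            (0.03, 0.003, 0.057),
            (0.197, 0.003, 0.391),
            (-0.079, -0.15, -0.008),
            (0.006, -0.002, 0.014),
        ),
    ]
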
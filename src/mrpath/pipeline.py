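"""Workflow orchestration: univariable screen, reverse-direction MR,
multivariable models and mediation tables.

These functions chain the lower-level modules exactly the way an analyst
would by hand: instrument selection → harmonization → the five
estimators → sensitivity diagnostics → primary-estimate choice, then
(for candidate mediators passing the significance gates on both path
legs) a two-exposure multivariable model and the product-of-coefficients
mediation summary. Every stochastic step (bootstrap SEs) draws its seed
deterministically from the run seed, so a run's manifest fully
determines its outputs.

No multiple-testing correction is applied by default (screening
significance is declared at p < alpha per test); a Benjamini–Hochberg
flag is available for reuse on wide screens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .errors import MRPathError
from .estimators import (
    EGGER,
    IVW_FIXED,
    IVW_RANDOM,
    MREstimate,
    SIMPLE_MODE,
    WEIGHTED_MEDIAN,
    WEIGHTED_MODE,
    all_estimates,
    select_primary,
)
from .instruments import FORWARD, REVERSE, HarmonizedSet, InstrumentConfig, harmonize, select_instruments
from .mediation import (
    COMPLETE,
    MediationInput,
    MediationResult,
    PARTIAL,
    run_mediation,
)
from .mvmr import MVMRModel, build_mvmr_set, mvmr_ivw
from .sensitivity import (
    HeterogeneityReport,
    PleiotropyTest,
    SteigerResult,
    cochran_q,
    egger_intercept_test,
    funnel_data,
    leave_one_out,
    steiger,
)
from .sumstats import SummaryStats, make_result_row, write_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int
    alpha: float = 0.05
    forward: InstrumentConfig = field(default_factory=lambda: FORWARD)
    reverse: InstrumentConfig = field(default_factory=lambda: REVERSE)
    n_boot: int = 1000
    palindromic_policy: str = "infer"
    adjust_pvalues: bool = False
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PairResult:
    exposure: str
    outcome: str
    harmonized: HarmonizedSet | None = None
    estimates: dict[str, MREstimate] | None = None
    primary: MREstimate | None = None
    heterogeneity: HeterogeneityReport | None = None
    pleiotropy: PleiotropyTest | None = None
    loo: pd.DataFrame | None = None
    funnel: pd.DataFrame | None = None
    steiger: SteigerResult | None = None
    significant: bool | None = None
    error: str | None = None


@dataclass
class ScreenResult:
    pairs: list[PairResult]
    estimates_table: pd.DataFrame
    primary_table: pd.DataFrame


def _analyse_pair(
    exp: SummaryStats,
    out: SummaryStats,
    cfg: RunConfig,
    icfg: InstrumentConfig,
    seed: int,
    ld=None,
    positions=None,
) -> PairResult:
    res = PairResult(exp.trait_id, out.trait_id)
    inst = select_instruments(exp, icfg, ld=ld, positions=positions)
    h = harmonize(inst, out, cfg.palindromic_policy, icfg)
    res.harmonized = h
    res.estimates = all_estimates(h, n_boot=cfg.n_boot, seed=seed)
    res.heterogeneity = cochran_q(h)
    res.pleiotropy = egger_intercept_test(res.estimates["egger"])
    res.primary = select_primary(res.estimates, res.heterogeneity, res.pleiotropy)
    if h.nsnp >= 3:
        res.loo = leave_one_out(h)
    res.funnel = funnel_data(h)
    try:
        res.steiger = steiger(h)
    except MRPathError as exc:
        logger.info("steiger skipped for %s: %s", exp.trait_id, exc)
    res.significant = bool(res.primary.pval < cfg.alpha)
    return res


def _screen(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    cfg: RunConfig,
    icfg: InstrumentConfig,
    ld=None,
    positions=None,
) -> ScreenResult:
    rng = np.random.default_rng(cfg.seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=len(exposures))
    pairs: list[PairResult] = []
    for exp, seed in zip(exposures, pair_seeds):
        try:
            pairs.append(
                _analyse_pair(exp, outcome, cfg, icfg, int(seed), ld, positions)
            )
        except MRPathError as exc:
            logger.warning("pair %s -> %s failed: %s", exp.trait_id, outcome.trait_id, exc)
            pairs.append(
                PairResult(exp.trait_id, outcome.trait_id, error=str(exc))
            )

    method_rows, primary_rows = [], []
    for p in pairs:
        if p.error:
            continue
        # five-method view: the IVW row is the variant the heterogeneity
        # test selects, alongside Egger, weighted median and both modes
        ivw_label = IVW_RANDOM if p.heterogeneity.pval < 0.05 else IVW_FIXED
        for name in (ivw_label, EGGER, WEIGHTED_MEDIAN, SIMPLE_MODE, WEIGHTED_MODE):
            method_rows.append(make_result_row(p.exposure, p.outcome, p.estimates[name]))
        row = make_result_row(p.exposure, p.outcome, p.primary)
        row.update(
            {
                "q_pval": p.heterogeneity.pval,
                "i2": p.heterogeneity.i2,
                "egger_intercept_pval": p.pleiotropy.pval,
                "significant": p.significant,
            }
        )
        primary_rows.append(row)
    estimates_table = pd.DataFrame(method_rows)
    primary_table = pd.DataFrame(primary_rows)
    if cfg.adjust_pvalues and len(primary_table):
        adj = multipletests(primary_table["pval"], alpha=cfg.alpha, method="fdr_bh")
        primary_table["pval_adj"] = adj[1]
        primary_table["significant"] = adj[0]
        for p, sig in zip([q for q in pairs if not q.error], adj[0]):
            p.significant = bool(sig)
    return ScreenResult(pairs, estimates_table, primary_table)


def run_univariable_screen(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    cfg: RunConfig,
    ld=None,
    positions=None,
) -> ScreenResult:
    """Forward univariable MR of every exposure on the outcome, with the
    full estimator suite and sensitivity diagnostics per pair. Failed
    pairs are logged and carried as error records, not raised."""
    return _screen(exposures, outcome, cfg, cfg.forward, ld, positions)


def run_reverse_mr(
    outcome: SummaryStats,
    traits: list[SummaryStats],
    cfg: RunConfig,
    ld=None,
    positions=None,
) -> ScreenResult:
    """Reverse-direction MR: the outcome, instrumented at the relaxed
    threshold preset, against each prior exposure/mediator."""
    return _reverse(outcome, traits, cfg, ld, positions)


def _reverse(outcome, traits, cfg, ld, positions) -> ScreenResult:
    rng = np.random.default_rng(cfg.seed + 1)
    seeds = rng.integers(0, 2**31 - 1, size=len(traits))
    pairs = []
    for trait, seed in zip(traits, seeds):
        try:
            pairs.append(
                _analyse_pair(outcome, trait, cfg, cfg.reverse, int(seed), ld, positions)
            )
        except MRPathError as exc:
            logger.warning("reverse pair %s -> %s failed: %s", outcome.trait_id, trait.trait_id, exc)
            pairs.append(PairResult(outcome.trait_id, trait.trait_id, error=str(exc)))
    method_rows, primary_rows = [], []
    for p in pairs:
        if p.error:
            continue
        ivw_label = IVW_RANDOM if p.heterogeneity.pval < 0.05 else IVW_FIXED
        for name in (ivw_label, EGGER, WEIGHTED_MEDIAN, SIMPLE_MODE, WEIGHTED_MODE):
            method_rows.append(make_result_row(p.exposure, p.outcome, p.estimates[name]))
        primary_rows.append(make_result_row(p.exposure, p.outcome, p.primary))
    return ScreenResult(pairs, pd.DataFrame(method_rows), pd.DataFrame(primary_rows))


@dataclass
class MediationModelResult:
    exposure: str
    mediator: str
    outcome: str
    mvmr: MVMRModel | None = None
    mvmr_results: pd.DataFrame | None = None
    inp: MediationInput | None = None
    result: MediationResult | None = None
    gate_failed: str | None = None


@dataclass
class MediationWorkflowResult:
    total: MREstimate
    models: list[MediationModelResult]
    mvmr_table: pd.DataFrame
    mediation_table: pd.DataFrame


def run_mediation_workflow(
    exposure: SummaryStats,
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    cfg: RunConfig,
    ld=None,
    positions=None,
) -> MediationWorkflowResult:
    """Two-step mediation: univariable legs, gate, MVMR, product method.

    For each candidate mediator both legs (exposure→mediator and
    mediator→outcome, univariable primaries) must be significant at
    ``cfg.alpha`` before a two-exposure multivariable model is fitted;
    the mediated effect is then β_A (univariable exposure→mediator) times
    β_B (mediator's MVMR direct effect), with the Aroian SE, mediation
    class and sign-dependent proportion. Only complete/partial models
    enter the mediation table.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    total_screen = _screen([exposure], outcome, cfg, cfg.forward, ld, positions)
    total_pair = total_screen.pairs[0]
    if total_pair.error:
        raise MRPathError(f"total-effect MR failed: {total_pair.error}")
    total = total_pair.primary

    models: list[MediationModelResult] = []
    mvmr_rows, mediation_rows = [], []
    for i, med in enumerate(mediators):
        m = MediationModelResult(exposure.trait_id, med.trait_id, outcome.trait_id)
        models.append(m)
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            leg_a = _analyse_pair(exposure, med, cfg, cfg.forward, seed, ld, positions)
            leg_b = _analyse_pair(med, outcome, cfg, cfg.forward, seed + 1, ld, positions)
        except MRPathError as exc:
            m.gate_failed = f"leg estimation failed: {exc}"
            logger.warning("mediator %s skipped: %s", med.trait_id, exc)
            continue
        if not leg_a.significant:
            m.gate_failed = "exposure->mediator not significant"
            continue
        if not leg_b.significant:
            m.gate_failed = "mediator->outcome not significant"
            continue

        model = build_mvmr_set(
            [exposure, med], outcome, cfg.forward, ld=ld, positions=positions,
            palindromic_policy=cfg.palindromic_policy,
        )
        res = mvmr_ivw(model)
        m.mvmr, m.mvmr_results = model, res
        for _, r in res.iterrows():
            mvmr_rows.append(
                {
                    "model": f"model{i + 1}",
                    "exposure": r["exposure"],
                    "outcome": r["outcome"],
                    "nsnp": r["nsnp"],
                    "beta": r["beta"],
                    "se": r["se"],
                    "pval": r["pval"],
                }
            )
        by_id = res.set_index("exposure")
        direct = by_id.loc[exposure.trait_id]
        med_direct = by_id.loc[med.trait_id]
        m.inp = MediationInput(
            beta_A=leg_a.primary.beta,
            se_A=leg_a.primary.se,
            beta_B=float(med_direct["beta"]),
            se_B=float(med_direct["se"]),
            beta_C=total.beta,
            se_C=total.se,
            beta_Cprime=float(direct["beta"]),
            se_Cprime=float(direct["se"]),
            p_A=leg_a.primary.pval,
            p_B=float(med_direct["pval"]),
            p_Cprime=float(direct["pval"]),
        )
        m.result = run_mediation(m.inp, cfg.alpha)
        if m.result.mediation_class in (COMPLETE, PARTIAL):
            mediation_rows.append(
                {
                    "exposure": exposure.trait_id,
                    "mediator": med.trait_id,
                    "outcome": outcome.trait_id,
                    "total_effect": total.beta,
                    "effect_em": m.inp.beta_A,
                    "effect_mo": m.inp.beta_B,
                    "effect_eo": m.inp.beta_Cprime,
                    "mediation_effect": m.result.beta_M,
                    "mediation_ci_low": m.result.ci_low,
                    "mediation_ci_high": m.result.ci_high,
                    "mediation_class": m.result.mediation_class,
                    "proportion_pct": m.result.proportion,
                    "denominator_used": m.result.denominator_used,
                }
            )

    return MediationWorkflowResult(
        total=total,
        models=models,
        mvmr_table=pd.DataFrame(mvmr_rows),
        mediation_table=pd.DataFrame(mediation_rows),
    )


def write_manifest(path, cfg: RunConfig, screens: list[ScreenResult] | None = None) -> dict:
    """JSON run manifest: seed, thresholds, versions and the per-pair
    primary-estimator decisions; fully determines every output byte."""
    decisions = []
    for screen in screens or []:
        for p in screen.pairs:
            decisions.append(
                {
                    "exposure": p.exposure,
                    "outcome": p.outcome,
                    "primary_method": p.primary.method if p.primary else None,
                    "error": p.error,
                }
            )
    manifest = {
        "mrpath_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "forward_p_threshold": cfg.forward.p_threshold,
        "reverse_p_threshold": cfg.reverse.p_threshold,
        "r2_max": cfg.forward.r2_max,
        "window_kb": cfg.forward.window_kb,
        "n_boot": cfg.n_boot,
        "palindromic_policy": cfg.palindromic_policy,
        "adjust_pvalues": cfg.adjust_pvalues,
        "decisions": decisions,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_screen_tables(screen: ScreenResult, outdir) -> None:
    """Write the method-level and primary result tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(screen.estimates_table):
        write_table(screen.estimates_table, outdir / "estimates.tsv")
    if len(screen.primary_table):
        write_table(screen.primary_table, outdir / "primary.tsv")
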
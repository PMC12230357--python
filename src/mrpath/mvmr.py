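"""Multivariable MR: joint direct effects of several exposures on one
outcome from summary statistics.

The instrument set is the union of each exposure's instruments, clumped
jointly on the pooled candidate list, with every trait's effects
harmonized to a common effect allele; a SNP absent from any trait's table
is dropped. The direct effects come from a zero-intercept weighted
multiple regression of outcome betas on all exposure beta columns
(weights 1/se_out²) — the summary-data analogue of two-stage least
squares with multiple exposures.

Per-exposure instrument counts are bookkept by origin: each design SNP is
attributed to the exposure whose instrument list it came from (ties go to
the smaller p-value), which is why reported nSNP differs between
exposures sharing one design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError, NoInstrumentsError
from .instruments import FORWARD, InstrumentConfig, harmonize, select_instruments
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class MVMRModel:
    """Design and (after fitting) results of one multivariable MR model."""

    exposure_ids: list[str]
    outcome_id: str
    data: pd.DataFrame  # snp, beta_<id>, se_<id>..., beta_out, se_out, origin
    results: pd.DataFrame | None = field(default=None)

    @property
    def nsnp(self) -> int:
        return len(self.data)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = self.data[[f"beta_{t}" for t in self.exposure_ids]].to_numpy(float)
        y = self.data["beta_out"].to_numpy(float)
        w = 1.0 / self.data["se_out"].to_numpy(float) ** 2
        return X, y, w


def build_mvmr_set(
    exps: list[SummaryStats],
    out: SummaryStats,
    cfg: InstrumentConfig = FORWARD,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    palindromic_policy: str = "infer",
) -> MVMRModel:
    """Union-of-instruments multivariable design.

    Each exposure's instruments are selected at ``cfg``; the pooled list
    (deduplicated, each SNP attributed to the exposure where it is most
    significant) is re-clumped jointly, then every trait's effects are
    aligned to the attributed exposure's effect allele. SNPs missing from
    any trait are dropped with a log entry.
    """
    if len(exps) < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    ids = [e.trait_id for e in exps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate exposure trait_ids")

    # pool instruments; attribute each SNP to its most-significant exposure
    pooled: dict[str, tuple[float, int]] = {}
    any_instruments = False
    for i, exp in enumerate(exps):
        try:
            inst = select_instruments(exp, cfg, ld=ld, positions=positions)
        except NoInstrumentsError:
            logger.warning("%s: no instruments at p<%g", exp.trait_id, cfg.p_threshold)
            continue
        any_instruments = True
        for _, row in inst.data.iterrows():
            prev = pooled.get(row["snp"])
            if prev is None or row["pval"] < prev[0]:
                pooled[row["snp"]] = (float(row["pval"]), i)
    if not any_instruments or not pooled:
        raise NoInstrumentsError("no exposure contributes instruments")

    # joint re-clump of the pooled list (by ascending best p)
    ref_rows = []
    for snp, (pval, i) in pooled.items():
        rec = exps[i].data.loc[exps[i].data["snp"] == snp].iloc[0].copy()
        rec["pval"] = pval
        rec["_origin"] = ids[i]
        ref_rows.append(rec)
    ref_df = pd.DataFrame(ref_rows).reset_index(drop=True)
    origin = ref_df.set_index("snp")["_origin"]
    ref = SummaryStats("_pooled", ref_df.drop(columns=["_origin"]))
    ref = select_instruments(ref, cfg, ld=ld, positions=positions)

    # harmonize every trait to the pooled reference orientation
    design = ref.data[["snp"]].copy()
    for trait in [*exps, out]:
        shared = set(trait.data["snp"])
        missing = [s for s in design["snp"] if s not in shared]
        if missing:
            logger.info(
                "%s: %d pooled SNPs absent, dropped from MVMR design",
                trait.trait_id,
                len(missing),
            )
        h = harmonize(ref.subset([s for s in design["snp"] if s in shared]),
                      trait, palindromic_policy)
        kept = h.kept[["snp", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_{trait.trait_id}",
                     "se_out": f"se_{trait.trait_id}"}
        )
        design = design.merge(kept, on="snp", how="inner")

    design = design.rename(
        columns={f"beta_{out.trait_id}": "beta_out", f"se_{out.trait_id}": "se_out"}
    )
    design["origin"] = origin.loc[design["snp"]].to_numpy()
    if design.empty:
        raise NoInstrumentsError("empty MVMR design after harmonization")
    return MVMRModel(ids, out.trait_id, design.reset_index(drop=True))


def mvmr_ivw(model: MVMRModel) -> pd.DataFrame:
    """Fit the multivariable IVW regression; returns per-exposure rows
    (exposure, nsnp, beta, se, pval) and stores them on ``model.results``.

    p-values are t-based with df = nsnp − k. When the model's Cochran Q
    (df = nsnp − k) is significant at 0.05, SEs are inflated by
    sqrt(max(1, Q/df)) (multiplicative random effects). An identically
    zero exposure column yields a zero estimate with infinite SE; any
    other rank deficiency raises :class:`CollinearityError`.
    """
    k = len(model.exposure_ids)
    X, y, w = model.design()
    n = len(y)
    if n < k + 1:
        raise InsufficientInstrumentsError(k + 1, n)

    zero_cols = np.where(~X.any(axis=0))[0]
    active = [i for i in range(k) if i not in zero_cols]
    Xa = X[:, active]
    sw = np.sqrt(w)
    if active and np.linalg.matrix_rank(Xa * sw[:, None]) < len(active):
        raise CollinearityError([model.exposure_ids[i] for i in active])

    beta = np.zeros(k)
    se = np.full(k, np.inf)
    if active:
        fit = sm.WLS(y, Xa, weights=w).fit()
        q = float(np.sum(w * (y - Xa @ fit.params) ** 2))
        df = n - len(active)
        scale = 1.0
        if stats.chi2.sf(q, df) < 0.05:
            scale = max(1.0, q / df)
        bse = np.sqrt(scale * np.diag(fit.normalized_cov_params))
        for j, i in enumerate(active):
            beta[i] = fit.params[j]
            se[i] = bse[j]

    df = n - k
    tvals = np.divide(beta, se, out=np.zeros(k), where=np.isfinite(se) & (se > 0))
    pvals = np.where(np.isfinite(se), 2 * stats.t.sf(np.abs(tvals), df), 1.0)

    counts = model.data["origin"].value_counts()
    results = pd.DataFrame(
        {
            "exposure": model.exposure_ids,
            "outcome": model.outcome_id,
            "nsnp": [int(counts.get(t, 0)) for t in model.exposure_ids],
            "nsnp_design": n,
            "beta": beta,
            "se": se,
            "pval": pvals,
        }
    )
    model.results = results
    return results
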
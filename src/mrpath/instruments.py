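"""Instrument selection and exposure/outcome allele harmonization.

Instruments are chosen by a genome-wide significance threshold and greedy
LD clumping: candidates are walked in order of ascending p-value and a SNP
is kept unless it is in LD (r² above the clumping threshold) with an
already-kept SNP. When no LD matrix is available but physical positions
are, a distance window stands in for LD; with neither, instruments are
assumed independent and a loud warning is emitted (appropriate for
synthetic data generated without LD, wrong for real GWAS data).

Harmonization aligns the outcome table's effects to the exposure's effect
allele per SNP: same orientation is kept, swapped orientation flips the
outcome beta (and reflects its allele frequency), complementary-strand
records are complemented first, and palindromic SNPs (A/T, C/G) are
handled by policy — dropped, kept as-is, or orientation-inferred from the
allele frequencies when both are informative (outside the ambiguity
window 0.42–0.58).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyIntersectionError, NoInstrumentsError
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window in which a palindromic SNP's orientation cannot be inferred
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

# harmonization actions
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_MISMATCH = "dropped-mismatch"


@dataclass(frozen=True)
class InstrumentConfig:
    """Instrument-selection thresholds.

    The forward preset uses genome-wide significance (5e-8); reverse-
    direction analyses use the relaxed 5e-6 preset. Clumping removes SNPs
    with r² ≥ ``r2_max`` (or within ``window_kb`` of a kept SNP when only
    positions are available).
    """

    p_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


FORWARD = InstrumentConfig()
REVERSE = InstrumentConfig(p_threshold=5e-6)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele per SNP.

    ``data`` has one row per shared SNP with columns snp, beta_exp, se_exp,
    beta_out, se_out, eaf_exp, eaf_out, n_exp, n_out and ``action``
    (kept / flipped / dropped-palindromic / dropped-mismatch). Only
    kept/flipped rows enter estimation (:attr:`kept`).
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    palindromic_policy: str = "infer"
    config: InstrumentConfig | None = None

    @property
    def kept(self) -> pd.DataFrame:
        return self.data[self.data["action"].isin([KEPT, FLIPPED])].reset_index(
            drop=True
        )

    @property
    def nsnp(self) -> int:
        return len(self.kept)

    def drop_snps(self, snps) -> "HarmonizedSet":
        mask = ~self.data["snp"].isin([s.lower() for s in snps])
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.data[mask].reset_index(drop=True),
            self.palindromic_policy,
            self.config,
        )


def select_instruments(
    exp: SummaryStats,
    cfg: InstrumentConfig = FORWARD,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
) -> SummaryStats:
    """Significant, approximately independent instruments for one exposure.

    SNPs with p < ``cfg.p_threshold`` are greedily clumped by ascending
    p-value. ``ld`` is a symmetric SNP×SNP r² matrix (ids on both axes);
    ``positions`` is a frame with columns snp/chrom/bp. With neither, all
    significant SNPs are kept under an explicit independence warning.

    Raises :class:`NoInstrumentsError` when nothing passes the threshold.
    """
    cand = exp.data[exp.data["pval"] < cfg.p_threshold]
    if cand.empty:
        raise NoInstrumentsError(
            f"{exp.trait_id}: no SNP with p < {cfg.p_threshold:g}"
        )
    cand = cand.sort_values(["pval", "snp"], kind="mergesort")

    if ld is None and positions is None:
        logger.warning(
            "%s: no LD matrix or positions supplied; independence assumed "
            "across %d instruments",
            exp.trait_id,
            len(cand),
        )
        kept_ids = list(cand["snp"])
    elif ld is not None:
        ld = ld.copy()
        ld.index = ld.index.astype(str).str.lower()
        ld.columns = ld.columns.astype(str).str.lower()
        kept_ids = []
        for snp in cand["snp"]:
            in_ld = any(
                snp in ld.index
                and k in ld.columns
                and float(ld.loc[snp, k]) >= cfg.r2_max
                for k in kept_ids
            )
            if not in_ld:
                kept_ids.append(snp)
    else:
        pos = positions.copy()
        pos["snp"] = pos["snp"].astype(str).str.lower()
        pos = pos.set_index("snp")
        kept_ids = []
        for snp in cand["snp"]:
            if snp not in pos.index:
                kept_ids.append(snp)  # unknown position: cannot clump
                continue
            chrom, bp = pos.loc[snp, "chrom"], float(pos.loc[snp, "bp"])
            near = any(
                k in pos.index
                and pos.loc[k, "chrom"] == chrom
                and abs(float(pos.loc[k, "bp"]) - bp) <= cfg.window_kb * 1000
                for k in kept_ids
            )
            if not near:
                kept_ids.append(snp)

    return exp.subset(kept_ids)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _harmonize_row(row, policy: str):
    """Classify one shared SNP; returns (action, flip_needed)."""
    ea_e, oa_e = row["effect_allele_exp"], row["other_allele_exp"]
    ea_o, oa_o = row["effect_allele_out"], row["other_allele_out"]

    if _is_palindromic(ea_e, oa_e):
        if policy == "drop":
            return DROPPED_PALINDROMIC, False
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return DROPPED_MISMATCH, False
        if policy == "keep":
            return (KEPT, False) if ea_o == ea_e else (FLIPPED, True)
        # infer orientation from allele frequencies
        f_e, f_o = row["eaf_exp"], row["eaf_out"]
        lo, hi = PALINDROMIC_EAF_WINDOW
        if (
            pd.isna(f_e)
            or pd.isna(f_o)
            or lo <= f_e <= hi
            or lo <= f_o <= hi
        ):
            return DROPPED_PALINDROMIC, False
        # outcome eaf refers to its own effect allele; put on exposure's
        f_o_aligned = f_o if ea_o == ea_e else 1 - f_o
        same_side = (f_e > 0.5) == (f_o_aligned > 0.5)
        if same_side:
            return (KEPT, False) if ea_o == ea_e else (FLIPPED, True)
        # frequencies disagree: the outcome record is on the other strand,
        # which for a palindromic SNP swaps the allele roles
        return (FLIPPED, True) if ea_o == ea_e else (KEPT, False)

    # non-palindromic: try direct match, then strand complement
    for flip_strand in (False, True):
        a, b = (ea_o, oa_o) if not flip_strand else (
            COMPLEMENT[ea_o],
            COMPLEMENT[oa_o],
        )
        if (a, b) == (ea_e, oa_e):
            return KEPT, False
        if (a, b) == (oa_e, ea_e):
            return FLIPPED, True
    return DROPPED_MISMATCH, False


def harmonize(
    exp: SummaryStats,
    out: SummaryStats,
    palindromic_policy: str = "infer",
    cfg: InstrumentConfig | None = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per shared SNP."""
    if palindromic_policy not in ("keep", "drop", "infer"):
        raise ValueError("palindromic_policy must be keep|drop|infer")
    merged = exp.data.merge(
        out.data, on="snp", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise EmptyIntersectionError(
            f"{exp.trait_id} and {out.trait_id} share no SNPs"
        )

    actions, flips = [], []
    for _, row in merged.iterrows():
        action, flip = _harmonize_row(row, palindromic_policy)
        actions.append(action)
        flips.append(flip)
    merged["action"] = actions
    flips = np.asarray(flips)

    merged.loc[flips, "beta_out"] = -merged.loc[flips, "beta_out"]
    merged.loc[flips, "eaf_out"] = 1 - merged.loc[flips, "eaf_out"]

    n_flip = int(flips.sum())
    n_drop = int((~merged["action"].isin([KEPT, FLIPPED])).sum())
    if n_flip or n_drop:
        logger.info(
            "harmonize %s/%s: %d flipped, %d dropped of %d shared SNPs",
            exp.trait_id,
            out.trait_id,
            n_flip,
            n_drop,
            len(merged),
        )

    cols = [
        "snp",
        "beta_exp",
        "se_exp",
        "beta_out",
        "se_out",
        "eaf_exp",
        "eaf_out",
        "n_exp",
        "n_out",
        "action",
    ]
    return HarmonizedSet(
        exp.trait_id, out.trait_id, merged[cols], palindromic_policy, cfg
    )
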
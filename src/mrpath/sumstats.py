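"""Reading, validating and writing GWAS summary-statistics and result tables.

A summary-statistics table holds one trait's per-SNP marginal effects, in the
shape exported by IEU OpenGWAS and most consortium flat files: one row per
variant with the effect allele, the other allele, the per-allele effect
(log-odds for binary traits), its standard error, the p-value and, where
available, the effect-allele frequency and GWAS sample size.

Column-name synonyms are resolved through a fixed alias map (documented in
:data:`COLUMN_ALIASES`); unknown extra columns are carried through untouched.
Variant ids are compared case-insensitively and stored lower-cased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyTableError, MissingColumnError, NoValidRowsError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary statistics
CANONICAL_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

#: fixed alias map for IEU-style header variants (all matched lower-case)
COLUMN_ALIASES: dict[str, str] = {
    "snp": "snp",
    "rsid": "snp",
    "variant_id": "snp",
    "markername": "snp",
    "effect_allele": "effect_allele",
    "a1": "effect_allele",
    "ea": "effect_allele",
    "other_allele": "other_allele",
    "a2": "other_allele",
    "oa": "other_allele",
    "non_effect_allele": "other_allele",
    "eaf": "eaf",
    "effect_allele_freq": "eaf",
    "effect_allele_frequency": "eaf",
    "af": "eaf",
    "freq": "eaf",
    "beta": "beta",
    "b": "beta",
    "effect": "beta",
    "se": "se",
    "standard_error": "se",
    "stderr": "se",
    "pval": "pval",
    "p": "pval",
    "pvalue": "pval",
    "p_value": "pval",
    "n": "n",
    "samplesize": "n",
    "sample_size": "n",
}

#: fixed column order for causal-estimate result tables (forest-plot-ready)
RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "nsnp",
    "beta",
    "se",
    "pval",
    "or_",
    "or_ci_low",
    "or_ci_high",
]

_RESULT_FLOAT_COLUMNS = ["beta", "se", "pval", "or_", "or_ci_low", "or_ci_high"]


@dataclass
class SummaryStats:
    """One GWAS trait's validated per-SNP effect table.

    ``data`` always carries the canonical columns of
    :data:`CANONICAL_COLUMNS`; ``eaf`` and ``n`` may be NaN when the source
    did not provide them. ``n_dropped`` counts rows removed by validation.
    """

    trait_id: str
    data: pd.DataFrame
    n_dropped: int = 0
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    @property
    def nsnp(self) -> int:
        return len(self.data)

    @property
    def has_eaf(self) -> bool:
        return bool(self.data["eaf"].notna().all()) and self.nsnp > 0

    @property
    def has_n(self) -> bool:
        return bool(self.data["n"].notna().all()) and self.nsnp > 0

    def subset(self, snps) -> "SummaryStats":
        """Rows for the given SNP ids (order of ``snps`` preserved)."""
        idx = self.data.set_index("snp")
        wanted = [s.lower() for s in snps]
        sub = idx.loc[wanted].reset_index()
        return SummaryStats(self.trait_id, sub[self.data.columns])


def _resolve_columns(columns) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        canon = COLUMN_ALIASES.get(str(col).strip().lower())
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    return mapping


def validate_frame(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the summary-statistics invariants.

    Enforced: alleles in {A,C,G,T} and distinct, se > 0, pval in (0, 1],
    finite beta, eaf (when present) in [0, 1], n (when present) > 0, and
    unique SNP ids (first occurrence kept).
    """
    df = df.copy()
    df["snp"] = df["snp"].astype(str).str.strip().str.lower()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
    )
    ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    ok &= df["n"].isna() | (df["n"] > 0)
    ok &= ~df["snp"].duplicated(keep="first")

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d/%d rows failing validation", trait_id, n_dropped, len(df)
        )
    return df[ok], n_dropped


def from_frame(df: pd.DataFrame, trait_id: str) -> SummaryStats:
    """Build validated :class:`SummaryStats` from any alias-named frame."""
    mapping = _resolve_columns(df.columns)
    df = df.rename(columns=mapping)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(col)
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    clean, n_dropped = validate_frame(df[CANONICAL_COLUMNS + extra], trait_id)
    if clean.empty:
        raise NoValidRowsError(f"{trait_id}: no row passed validation")
    if clean["eaf"].isna().any():
        logger.info(
            "%s: eaf missing for %d SNPs; palindromic-frequency checks disabled "
            "for those variants",
            trait_id,
            int(clean["eaf"].isna().sum()),
        )
    return SummaryStats(trait_id, clean, n_dropped=n_dropped, extra_columns=extra)


def read_sumstats(path, trait_id: str) -> SummaryStats:
    """Read a tab- or comma-delimited summary-statistics file.

    The delimiter is sniffed from the header line; headers are matched
    against :data:`COLUMN_ALIASES`. Rows failing validation are dropped and
    counted; a missing mandatory column or an all-invalid file is a hard
    error.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return from_frame(df, trait_id)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write canonical tab-delimited summary statistics."""
    ss.data.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV in fixed column order.

    Floats are serialized at full precision; a parallel ``*_4dp`` display
    column set rounded to 4 decimals is appended for human readers.
    """
    if table is None or len(table) == 0:
        raise EmptyTableError("refusing to write an empty result table")
    out = table.copy()
    ordered = [c for c in RESULT_COLUMNS if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    out = out[ordered]
    for col in _RESULT_FLOAT_COLUMNS:
        if col in out.columns:
            out[col + "_4dp"] = np.round(pd.to_numeric(out[col]), 4)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (canonical columns)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df[[c for c in df.columns if not c.endswith("_4dp")]]


def make_result_row(
    exposure: str, outcome: str, est
) -> dict:
    """Flatten an :class:`~mrpath.estimators.MREstimate` into a result row."""
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "nsnp": est.nsnp,
        "beta": est.beta,
        "se": est.se,
        "pval": est.pval,
        "or_": est.or_,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
    }
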
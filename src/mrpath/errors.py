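"""Typed errors raised across the pipeline."""


class MRPathError(Exception):
    """Base class for all package errors."""


class MissingColumnError(MRPathError):
    """A mandatory summary-statistics column is absent."""

    def __init__(self, column: str) -> None:
        self.column = column
        super().__init__(f"mandatory column {column!r} not found (no alias matched)")


class NoValidRowsError(MRPathError):
    """Every row of an input table failed validation."""


class EmptyTableError(MRPathError):
    """A result table to be written contains no rows."""


class NoInstrumentsError(MRPathError):
    """No SNP passes the instrument p-value threshold."""


class EmptyIntersectionError(MRPathError):
    """Exposure and outcome tables share no SNP ids."""


class InsufficientInstrumentsError(MRPathError):
    """Fewer instruments than the estimator's minimum."""

    def __init__(self, needed: int, got: int, hint: str = "") -> None:
        msg = f"estimator needs >= {needed} instruments, got {got}"
        if hint:
            msg += f"; {hint}"
        super().__init__(msg)


class CollinearityError(MRPathError):
    """The multivariable design matrix is rank deficient."""

    def __init__(self, exposures) -> None:
        self.exposures = list(exposures)
        super().__init__(
            "rank-deficient MVMR design; collinear exposures: "
            + ", ".join(self.exposures)
        )


class MissingSampleSizeError(MRPathError):
    """A trait lacks the per-SNP sample sizes needed by the Steiger test."""

    def __init__(self, trait: str) -> None:
        self.trait = trait
        super().__init__(f"trait {trait!r} has no sample-size (n) column")


class DegenerateConfigError(MRPathError):
    """A simulation configuration is internally inconsistent."""
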
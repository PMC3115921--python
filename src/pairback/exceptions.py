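"""Exception hierarchy for summary-recovery failures.

Every failure mode a reported summary can trigger maps to one of these, so
batch processing can classify row-level failures by type.
"""


class PairbackError(ValueError):
    """Base class for all recovery errors."""


class DomainError(PairbackError):
    """An input is outside its mathematical domain (e.g. p not in (0, 1])."""


class OverflowPError(DomainError):
    """A p-value below the configured floor; the deviate would overflow."""


class DegenerateInputError(PairbackError):
    """A formally valid input for which the quantity is undefined.

    Examples: p = 1 (zero deviate, standard error unrecoverable); b + c = 0
    (McNemar statistic undefined).
    """


class InconsistencyError(PairbackError):
    """Mutually contradictory summaries (e.g. zero difference with p < 1)."""


class InfeasibleSummaryError(PairbackError):
    """Reported summaries that cannot come from any non-negative table."""


class SparseDataWarning(UserWarning):
    """Recovery is valid but the data are sparse or the study is small.

    Emitted when n <= 50, a discordant cell is <= 5, or the discordant
    fraction is <= 0.05: with few pairs or skewed tables, different CI
    methods diverge and back-calculated intervals should be read cautiously.
    """


class ClampedCellWarning(UserWarning):
    """A raw reconstructed cell in (-0.5, 0) was clamped to zero."""
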
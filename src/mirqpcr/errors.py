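"""Exception hierarchy shared across the package."""


class MirqpcrError(Exception):
    """Base class for all errors raised by mirqpcr."""


class FormatError(MirqpcrError):
    """A file violates the expected tabular structure (duplicates, empty, bad header)."""


class CtParseError(FormatError):
    """A Ct cell is neither numeric nor a recognised not-detected marker."""


class SampleSheetError(MirqpcrError):
    """Sample sheet inconsistent with the Ct table."""


class QCError(MirqpcrError):
    """Quality control cannot proceed (e.g. every sample excluded)."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class NormalizationError(MirqpcrError):
    """Reference controls unavailable for one or more samples."""


class DesignError(MirqpcrError):
    """Differential-expression design is unusable (missing groups, no analyzable rows)."""


class EnrichmentError(MirqpcrError):
    """Over-representation analysis cannot be set up (empty universe intersection)."""
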
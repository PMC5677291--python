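"""Exception hierarchy shared across the toolkit."""


class StressKitError(Exception):
    """Base class for all stresskit errors."""


class InvalidArgumentError(StressKitError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientPeaksError(StressKitError):
    """Fewer than two pulse peaks were found; NN intervals are undefined.

    Downstream this is handled by the missing-feature policy: the epoch is
    flagged and its features imputed from the subject-session median.
    """


class EmptySegmentError(StressKitError):
    """Epoching produced no epochs (signal shorter than the discard lead)."""


class NumericalError(StressKitError):
    """A linear system could not be solved despite ridge regularization."""
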
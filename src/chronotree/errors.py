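"""Exception hierarchy shared across the toolkit."""


class ChronotreeError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(ChronotreeError):
    """Malformed newick input (unbalanced parentheses, duplicate tips, bad lengths)."""


class InputError(ChronotreeError):
    """Malformed alignment / tabular input (ragged rows, unknown characters)."""


class ConfigurationError(ChronotreeError):
    """Inconsistent combination of tree, alignment and model."""


class ConstraintError(ChronotreeError):
    """Infeasible or contradictory calibration constraints."""


class EstimationError(ChronotreeError):
    """An estimation step failed (e.g. no temporal signal in tip dates)."""


class DegenerateInputError(ChronotreeError):
    """Input on which the requested statistic is undefined (e.g. a strict clock
    tree offered to the rate-autocorrelation test)."""
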
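"""Exception hierarchy for hcal."""


class HcalError(Exception):
    """Base class for all hcal errors."""


class InvalidArgumentError(HcalError, ValueError):
    """An argument violates a precondition (range, shape, pairing)."""


class MissingDataError(HcalError, LookupError):
    """Required cells, years, or ages are absent from the input data."""


class ParseError(HcalError, ValueError):
    """An input file does not conform to its declared format."""


class ConvergenceError(HcalError, RuntimeError):
    """An iterative fit failed to converge."""
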
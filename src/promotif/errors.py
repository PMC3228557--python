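"""Exception hierarchy shared across the package."""


class PromotifError(Exception):
    """Base class for all errors raised by promotif."""


class ValidationError(PromotifError, ValueError):
    """Invalid input data or parameters (bad file, bad counts, bad config)."""


class ParseError(ValidationError):
    """A file or motif string could not be parsed."""
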
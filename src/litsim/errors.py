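"""Exception hierarchy shared across the toolset."""


class LitsimError(Exception):
    """Base class for all litsim errors."""


class InputFormatError(LitsimError):
    """A file is not in the expected tab-delimited dialect."""


class ValidationError(LitsimError):
    """Input values violate a documented invariant or precondition."""


class RetrievalError(LitsimError):
    """A remote service could not be reached or kept failing after retries."""


class PayloadParseError(LitsimError):
    """A service payload could not be parsed into the expected structure."""
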
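"""Exception types shared across the pipeline stages."""


class NetcoverError(Exception):
    """Base class for all netcover errors."""


class ConfigurationError(NetcoverError):
    """A configuration field has an invalid value; the message names the field."""


class InputError(NetcoverError):
    """An input table or argument violates a stage precondition."""


class FormulaParseError(NetcoverError):
    """A molecular formula could not be parsed; the message gives the position."""
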
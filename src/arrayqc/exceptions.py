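"""Exception hierarchy for arrayqc."""


class ArrayQcError(Exception):
    """Base class for all arrayqc errors."""


class UnsupportedFormatError(ArrayQcError):
    """Input file is not in a format this package reads (bad magic, sample-major layout...)."""


class CorruptFilesetError(ArrayQcError):
    """File contents are inconsistent with the companion files (size/count mismatch)."""


class ParseError(ArrayQcError):
    """A text-format file could not be parsed; message carries file and line context."""


class DegenerateInputError(ArrayQcError):
    """An operation received an input it is undefined on (zero samples/variants...)."""


class ParameterError(ArrayQcError):
    """A parameter violates an operation's precondition."""
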
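"""Exception hierarchy shared across the pipeline."""


class CsfCtcError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CsfCtcError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(CsfCtcError):
    """Input violates a data-model invariant (negative count, duplicate ID...)."""


class MissingGenesError(CsfCtcError):
    """None of a gene set's members are present in the expression universe."""


class DegenerateInputError(CsfCtcError):
    """Input too small or too uniform for the requested statistic."""
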
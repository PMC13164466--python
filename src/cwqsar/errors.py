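"""Exception hierarchy for cwqsar."""


class CwqsarError(Exception):
    """Base class for all cwqsar errors."""


class MalformedSmilesError(CwqsarError):
    """A SMILES string cannot be tokenized or parsed into a graph.

    Carries the 0-based position of the offending character where known.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


class DataFormatError(CwqsarError):
    """A compound table, split file or model file is malformed."""


class DegenerateDescriptorError(CwqsarError):
    """The descriptor has zero variance; a line cannot be fitted."""


class ZeroVarianceError(CwqsarError):
    """A correlation-based statistic is undefined on constant input."""


class InvariantError(CwqsarError):
    """A precondition or internal invariant was violated."""
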
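"""Exception hierarchy shared across the toolkit."""


class SipracsError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(SipracsError, ValueError):
    """A design or function parameter violates its documented constraints."""


class InputError(SipracsError, ValueError):
    """Input data violate an operation's preconditions."""


class DegenerateInputError(InputError):
    """Input is structurally valid but degenerate (e.g. all-zero spectrum)."""


class FormatError(SipracsError, ValueError):
    """A file on disk does not conform to the expected dialect."""


class StageError(SipracsError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
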
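"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`MsigError`, so
callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class MsigError(Exception):
    """Base class for all msigkit errors."""


class ValidationError(MsigError, ValueError):
    """Input data violates a documented invariant (bad counts, duplicate ids...)."""


class SchemaMismatchError(ValidationError):
    """A channel label or channel set does not match the requested schema."""


class SampleLookupError(MsigError, KeyError):
    """A requested sample (or signature) id is not present."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ConvergenceError(MsigError, RuntimeError):
    """An iterative numerical routine exceeded its iteration budget."""
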
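"""Exception hierarchy shared across the package."""


class MeshblastError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MeshblastError):
    """A text input violated its declared dialect.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(MeshblastError):
    """Input parsed but violates a structural invariant (e.g. a taxonomy cycle)."""


class LinkResolutionError(MeshblastError):
    """A literature-link backend failed persistently for a batch of accessions."""

    def __init__(self, message: str, batch: tuple[str, ...] = ()):
        self.batch = batch
        super().__init__(message)
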
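"""Exception types shared across the package."""


class PolyburstError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PolyburstError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(PolyburstError, ValueError):
    """A value violates a documented invariant (range, sign, count)."""


class StateError(PolyburstError):
    """An operation was applied to an object in the wrong state
    (e.g. photobleaching correction applied twice)."""


class AmbiguousStartError(PolyburstError):
    """The first frame of a movie contains several spots and no initial
    choice was supplied to disambiguate the transcription site."""


class FitError(PolyburstError):
    """A numerical fit failed to converge; carries diagnostics in args."""
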
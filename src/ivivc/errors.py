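"""Exception hierarchy for the IVIVC toolkit."""


class IvivcError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(IvivcError):
    """An input table is missing a required column or has the wrong layout."""


class ProfileError(IvivcError):
    """A single profile violates its invariants (time ordering, ranges...)."""


class DatasetError(IvivcError):
    """A study dataset violates cross-profile invariants."""


class FitError(IvivcError):
    """A model fit failed to converge; carries best-attempt diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class DeconvolutionError(IvivcError):
    """The deconvolution linear system is unusable (ill-conditioned grid)."""
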
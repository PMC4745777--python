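"""Exception hierarchy shared across the package."""


class SynscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(SynscreenError):
    """The dose design cannot support the requested analysis."""


class DegenerateDataError(SynscreenError):
    """Response data carry no dose-response signal (e.g. all-constant)."""


class DomainError(SynscreenError, ValueError):
    """An argument lies outside the mathematical domain of a formula."""


class InvalidInputError(SynscreenError):
    """A structurally invalid object was passed (e.g. a non-converged fit)."""


class UndefinedResultError(SynscreenError):
    """The requested result is undefined for the given inputs."""


class UnusableDesignError(SynscreenError):
    """A simulation design that cannot produce usable data."""
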
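"""Exception hierarchy shared across the package.

All physically meaningful failure modes are typed so callers (and the CLI,
which maps them to exit code 3) can distinguish them from programming errors.
"""


class MonowetError(Exception):
    """Base class for all package errors."""


class DomainError(MonowetError, ValueError):
    """An input is outside the physically admissible domain."""


class NeverAdsorbsError(MonowetError):
    """The adsorption free energy is positive over the whole angle range.

    The bilayer is preferred on every substrate: no adsorption contact
    angle exists because no contact angle makes the monolayer stable.
    """


class AlwaysAdsorbsError(MonowetError):
    """The adsorption free energy is negative over the whole angle range.

    The monolayer is preferred on every substrate; the threshold angle has
    formally moved below 0 degrees.
    """


class NoEquivalentAngleError(MonowetError):
    """No solid-substrate contact angle matches the air-water free energy."""


class NoInterfaceError(MonowetError):
    """A density field contains no crossing of the requested iso-level."""


class DetachedDropletError(MonowetError):
    """The fitted circle does not intersect the substrate plane."""


class DegenerateFitError(MonowetError):
    """Too few or degenerate (e.g. collinear) points for a stable fit."""


class DataFormatError(MonowetError):
    """A data file violates the expected tabular/grid format."""
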
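"""Exception hierarchy for osmoflux.

All errors derive from :class:`OsmofluxError` so callers can catch the
package's failures with a single clause; most also derive from the matching
builtin (ValueError/KeyError) to behave naturally in generic code.
"""


class OsmofluxError(Exception):
    """Base class for all osmoflux errors."""


class InvalidInputError(OsmofluxError, ValueError):
    """A measurement or parameter violates a physical precondition."""


class ConfigurationError(OsmofluxError, ValueError):
    """Missing or inconsistent configuration (e.g. no virial coefficients
    and no directly supplied applied pressure)."""


class GeometryError(OsmofluxError, ValueError):
    """Radii ordering violated (r1 < r2 <= r3 required)."""


class ModelError(OsmofluxError, ValueError):
    """The model produced or received a physically impossible state
    (zero permeability, negative osmolality, lambda outside the validity
    range of the permeability law)."""


class CalibrationLookupError(OsmofluxError, KeyError):
    """No membrane calibration available for a probe."""


class SolverError(OsmofluxError, RuntimeError):
    """Root finding for the forward flux problem failed to bracket/converge."""


class SchemaError(OsmofluxError, ValueError):
    """A CSV is missing required columns."""
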
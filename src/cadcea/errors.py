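"""Exception hierarchy for the package.

All exceptions derive from :class:`CadCeaError` so callers can catch the
package's failures with a single clause; the subclasses distinguish invalid
numeric inputs, mis-specified configuration, and link-calibration failures.
"""


class CadCeaError(Exception):
    """Base class for all errors raised by cadcea."""


class DomainError(CadCeaError, ValueError):
    """A numeric input is outside its valid domain (e.g. a probability > 1)."""


class ConfigurationError(CadCeaError, ValueError):
    """A configuration object or file is invalid or incomplete."""


class CalibrationError(CadCeaError, ValueError):
    """Link calibration failed (too few points, or a non-monotone fit)."""
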
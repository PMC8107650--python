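"""Exception hierarchy.

All errors derive from :class:`KernemError` so callers can catch the
package's failures with a single clause; the CLI maps the subclasses to
distinct exit codes.
"""


class KernemError(Exception):
    """Base class for all package errors."""


class GeometryError(KernemError, ValueError):
    """Images/sinograms/masks with incompatible or invalid geometry."""


class ConfigurationError(KernemError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class ContractError(KernemError, ValueError):
    """An operation was called with arguments violating its contract."""


class MetricError(KernemError, ValueError):
    """A ROI metric is undefined for the given inputs (empty mask, zero mean...)."""


class SelectionError(KernemError, ValueError):
    """No candidate satisfied a selection rule (e.g. no sweep point in the CoV band)."""


class StatisticError(KernemError, ValueError):
    """A statistic is undefined for the given inputs (single class, zero variance...)."""


class IOFormatError(KernemError, IOError):
    """A file could not be read or did not match the expected layout."""
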
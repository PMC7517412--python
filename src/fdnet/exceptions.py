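"""Exception hierarchy for fdnet.

All fdnet errors derive from :class:`FdnetError` so callers can catch the
package's failures with a single ``except`` clause; each subclass marks a
distinct failure mode referenced in the CLI's exit handling.
"""


class FdnetError(Exception):
    """Base class for all fdnet errors."""


class AtlasIntegrityError(FdnetError):
    """Packaged atlas data does not match its recorded checksum."""


class DomainError(FdnetError, ValueError):
    """Input is structurally valid but outside an operation's domain
    (empty mask, all-zero network, too few subjects, ...)."""


class ValidationError(FdnetError, ValueError):
    """Malformed input: wrong shape, bad label codes, duplicated ids,
    non-numeric values, out-of-range parameters."""


class ConfigError(FdnetError, ValueError):
    """Invalid simulation or run configuration (e.g. non-PSD implied
    covariance)."""
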
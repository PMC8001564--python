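"""Exception hierarchy shared across the package.

All mrkit errors derive from :class:`MRKitError` so callers can catch the
package's failures with a single clause while still distinguishing
configuration mistakes (bad column maps, unknown exposures) from data
problems (malformed rows, allele ambiguity) and statistical degeneracies
(too few instruments, zero-variance scores).
"""

from __future__ import annotations


class MRKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRKitError):
    """A run/reader configuration is invalid (missing column, unknown key)."""


class DataError(MRKitError):
    """Input data violate a contract (malformed rows, duplicates)."""


class RowParseError(DataError):
    """One or more data rows failed to parse; carries (line, message) pairs."""

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = failures
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in failures[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        super().__init__(f"{len(failures)} malformed row(s): {detail}{more}")


class DomainError(MRKitError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class HarmonizationError(DataError):
    """Exposure and outcome statistics cannot be aligned."""


class InsufficientInstrumentsError(MRKitError):
    """An estimator was given fewer variants than it requires."""


class CollinearityError(MRKitError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")
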
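"""Exception hierarchy for milkpk.

All package errors derive from :class:`MilkPKError` so callers can catch
one base class; the leaf classes mirror the failure modes of each analysis
stage (schema vs. value validation, non-estimable terminal phase, pairing
mistakes, time-point capping, infeasible calibration targets).
"""


class MilkPKError(Exception):
    """Base class for all milkpk errors."""


class SchemaError(MilkPKError):
    """Input file does not have the expected tidy-CSV schema."""


class ValidationError(MilkPKError):
    """Input values violate a domain invariant (ordering, sign, uniqueness)."""


class NotEstimableError(MilkPKError):
    """A quantity (terminal slope, withdrawal time) cannot be estimated
    from the available data, e.g. too few quantifiable points or a
    non-negative terminal slope."""


class NotComputableError(MilkPKError):
    """A requested point value is unavailable (unsampled time or BLQ)."""


class PairingError(MilkPKError):
    """Two results/profiles that must refer to the same subject and dose
    do not."""


class CappingError(MilkPKError):
    """More distinct sampling times than the regression cap allows and no
    explicit exclusion list was given."""


class InsufficientDataError(MilkPKError):
    """Fewer usable observations than the operation requires."""


class CalibrationError(MilkPKError):
    """The simulator's calibration constraint system is infeasible."""


class WindowError(MilkPKError):
    """The withdrawal-time search window never falls below the cutoff."""
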
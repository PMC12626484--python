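"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes: usage/input problems
exit 1, data-validation problems exit 2, numerical failures exit 3.
"""


class GraftCalibError(Exception):
    """Base class for all package errors."""


class InputError(GraftCalibError):
    """Malformed arguments: length mismatches, degenerate grids, bad options."""


class DataValidationError(GraftCalibError):
    """Cohort files or records that violate the data contract."""


class CohortFormatError(DataValidationError):
    """Required columns missing or unparsable file structure."""


class EmptyCohortError(DataValidationError):
    """No usable donor rows remain after filtering."""


class NumericalError(GraftCalibError):
    """Statistics undefined for the given data (zero variance, n too small...)."""
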
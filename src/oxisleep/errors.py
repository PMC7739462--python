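"""Typed error hierarchy with stable CLI exit codes.

Every reader/writer and pipeline stage raises one of these instead of a
bare ValueError, so callers (and the CLI) can map failures to distinct
exit codes.
"""

from __future__ import annotations


class OxisleepError(Exception):
    """Base class; ``exit_code`` is what the CLI returns on this failure."""

    exit_code = 1


class InputIOError(OxisleepError):
    """Missing or unreadable input file."""

    exit_code = 3


class FormatError(OxisleepError):
    """Input exists but violates the expected format (bad timestamps,
    wrong columns, malformed EDF...)."""

    exit_code = 4


class ConfigError(OxisleepError):
    """Invalid or infeasible configuration values."""

    exit_code = 5


class StateError(OxisleepError):
    """Operation called out of order (e.g. predict before fit)."""

    exit_code = 6


class SchemaError(OxisleepError):
    """Persisted model/report JSON is corrupt or missing fields."""

    exit_code = 7


class TrainingError(OxisleepError):
    """Training preconditions violated (single-class data, class too
    small for stratification...)."""

    exit_code = 8
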
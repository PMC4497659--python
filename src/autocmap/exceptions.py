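"""Exception hierarchy for autocmap."""


class AutocmapError(Exception):
    """Base class for all package errors."""


class SchemaError(AutocmapError):
    """Malformed table: empty file, duplicate variable names, ragged rows."""


class CompletenessError(AutocmapError):
    """The input table contains missing values; every analysis here requires
    complete data, imputation is out of scope."""


class SpecError(AutocmapError):
    """Invalid synthetic-data specification (infeasible correlations,
    non-tree topology, degenerate sample sizes)."""


class NotScaledError(AutocmapError):
    """An operation required inputs in the unit interval [0, 1]."""
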
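"""Exception hierarchy shared across the package."""


class IonsiteError(Exception):
    """Base class for all ionsite-specific errors."""


class ParseError(IonsiteError):
    """A structure or data file could not be parsed."""


class StructureError(IonsiteError):
    """A trajectory file is internally inconsistent (e.g. atom counts differ across frames)."""


class SelectionError(IonsiteError):
    """An atom selection matched no atom, or more than one."""


class ScheduleError(IonsiteError):
    """Sample series and λ schedule do not describe the same windows."""


class DataError(IonsiteError):
    """Input data violate a precondition of the requested analysis."""


class InsufficientDataError(DataError):
    """Too few samples/blocks for the requested statistic."""


class OrientationError(IonsiteError):
    """Forward/backward estimates are not oriented as required."""
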
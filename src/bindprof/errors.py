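"""Exception hierarchy for the bindprof pipeline."""


class BindprofError(Exception):
    """Base class for all package errors."""


class FormatError(BindprofError):
    """Malformed structure/trajectory file."""


class ConfigError(BindprofError):
    """Invalid run configuration or group selectors."""


class TopologyError(BindprofError):
    """Chemically inconsistent topology (e.g. an unbonded hydrogen)."""


class SelectionError(BindprofError):
    """Selector expression could not be parsed or resolved."""


class ScheduleError(BindprofError):
    """Conflicting or invalid synthetic contact schedule."""


class ModeError(BindprofError):
    """Operation called in the wrong analysis mode (static vs trajectory)."""
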
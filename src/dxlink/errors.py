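"""Exception hierarchy shared by all dxlink modules.

The CLI maps these onto distinct exit codes so pipelines can tell a bad
input file (format), an input that violates a mathematical precondition
(e.g. a non-cubic graph fed to the truncation engine), and an internal
consistency failure (a theorem-level identity that did not hold) apart.
"""


class DxlinkError(Exception):
    """Base class for all dxlink errors."""


class GraphFormatError(DxlinkError):
    """Malformed graph file or builtin-name lookup failure."""


class PreconditionError(DxlinkError):
    """Input violates a documented mathematical precondition."""


class ConsistencyError(DxlinkError):
    """An internal identity that must hold by theorem failed to hold.

    Raising this instead of silently returning garbage turns a subtle
    math bug (or an invalid hand-built polynomial) into a loud failure.
    """
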
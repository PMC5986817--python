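"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`InsufficientDataError` -> 3, everything else -> 1.
"""


class TunnelcallError(Exception):
    """Base class for all package-specific errors."""


class InputError(TunnelcallError, ValueError):
    """Invalid user input (bad sequence, malformed parameters, ...)."""


class FormatError(TunnelcallError, ValueError):
    """A file does not conform to one of the on-disk formats."""


class FittingError(TunnelcallError, RuntimeError):
    """Conductance-histogram mixture fitting failed (e.g. insufficient
    peak separation)."""


class DegenerateNoiseError(TunnelcallError, RuntimeError):
    """Noise estimation produced a non-positive sigma, so thresholding is
    meaningless (typically a constant or near-constant trace)."""


class InsufficientDataError(TunnelcallError, RuntimeError):
    """Not enough events/fragments/placements to compute the statistic."""
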
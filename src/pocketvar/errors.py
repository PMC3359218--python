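"""Exception hierarchy.

Every error raised by the library derives from :class:`PocketvarError`, so
callers (and the CLI) can map failure classes to distinct exit codes.
"""


class PocketvarError(Exception):
    """Base class for all pocketvar errors."""


class ConfigError(PocketvarError):
    """Invalid run configuration (missing alignment, bad cutoff, ...)."""


class FormatError(PocketvarError):
    """Unparsable input file; message names the offending line where known."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        if path is not None:
            message = f"{path}: {message}"
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.path = path
        self.line_number = line_number


class EmptyStructureError(FormatError):
    """A structure file contained zero protein atoms."""


class EmptyPredictionError(FormatError):
    """A prediction file contained no parseable pocket points.

    Distinct from a *legitimately* empty prediction, which is constructed
    explicitly via :meth:`pocketvar.pocket_io.PocketPointSet.empty`.
    """


class PairingError(PocketvarError):
    """Structures and predictions could not be matched one-to-one."""


class TopologyError(PocketvarError):
    """Indicator vectors of supposedly same-topology structures disagree in length."""


class MappingError(PocketvarError):
    """Alignment/structure correspondence failure."""


class DataError(PocketvarError):
    """Invalid numeric data (NaN coordinates, zero-atom residue, ...)."""


class DegenerateDistributionError(PocketvarError):
    """Too few non-zero scores to compute quartiles."""
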
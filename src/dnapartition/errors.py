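"""Exception hierarchy for the partitioning pipeline."""


class PartitionError(Exception):
    """Base class for all errors raised by dnapartition."""


class DesignSizeError(PartitionError):
    """Input sequence exceeds the 10 Mb design size cap."""


class AlphabetError(PartitionError):
    """Input sequence contains characters outside {A, C, G, T}."""

    def __init__(self, positions, message=None):
        self.positions = list(positions)
        shown = ", ".join(str(p) for p in self.positions[:10])
        more = "" if len(self.positions) <= 10 else f" (+{len(self.positions) - 10} more)"
        super().__init__(
            message or f"non-ACGT characters at 0-based positions: {shown}{more}"
        )


class AnnotationError(PartitionError):
    """Part annotations are discontinuous, overlapping, gapped or missing."""


class ParameterError(PartitionError):
    """Partitioning parameters are infeasible or inconsistent."""


class CapViolationError(PartitionError):
    """An assembly unit exceeds (1 + tolerance) x its tier size limit."""


class FixtureError(PartitionError):
    """A synthetic fixture could not be generated under its constraints."""


class OutputError(PartitionError):
    """Output artifacts could not be written."""
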
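"""Exception hierarchy. Everything raised on purpose derives from FounderScanError."""


class FounderScanError(Exception):
    """Base class for all package errors."""


class ParseError(FounderScanError):
    """A file could not be parsed (malformed line, unknown column...)."""


class ValidationError(FounderScanError):
    """Parsed or constructed data violates an invariant."""


class ConfigError(FounderScanError):
    """An invalid configuration value."""


class MapLookupError(FounderScanError):
    """Chromosome absent from a genetic map."""


class EmptyCoreError(FounderScanError):
    """Cluster segments have an empty intersection."""


class NoSharedHaplotypeError(FounderScanError):
    """No single haplotype is carried by every cluster member over an interval."""


class AmbiguousHaplotypeError(FounderScanError):
    """More than one distinct haplotype is carried by every cluster member."""


class PipelineError(FounderScanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
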
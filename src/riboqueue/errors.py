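"""Exception hierarchy for riboqueue."""


class RiboQueueError(Exception):
    """Base class for all riboqueue errors."""


class ConfigurationError(RiboQueueError):
    """Invalid configuration (distributions that do not sum to one, bad ranges...)."""


class FormatError(RiboQueueError):
    """Malformed input file (offset table, annotation, alignments, GFF3)."""


class PipelineError(RiboQueueError):
    """Invalid stage list or missing upstream stage output."""
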
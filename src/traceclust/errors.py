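"""Exception types shared across the package."""


class TraceclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TraceclustError):
    """A configuration value is invalid; the message names the field."""


class FormatError(TraceclustError):
    """An input file does not have the expected shape (columns, token form)."""


class EmptyCorpusError(TraceclustError):
    """An operation that needs at least one event/document received none."""


class VocabularyMismatchError(TraceclustError):
    """Events or documents contain tokens absent from the given vocabulary."""


class NoCoactiveWeeksError(TraceclustError):
    """Two actors share no week in which both have positive activity."""


class PipelineStageError(TraceclustError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
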
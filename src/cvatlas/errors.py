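"""Exception hierarchy for the cvatlas pipeline."""


class CvAtlasError(Exception):
    """Base class for all cvatlas errors."""


class SchemaError(CvAtlasError):
    """An input table is missing a required column or has an unusable layout."""


class ScheduleMismatchError(CvAtlasError):
    """A well's measurement count does not match the injection schedule."""


class MissingPhaseError(CvAtlasError):
    """A required injection phase has no usable measurements."""


class GroupingError(CvAtlasError):
    """Wells grouped as one biological sample disagree on their metadata."""


class JoinError(CvAtlasError):
    """Activity records and MTDR readings could not be matched one-to-one."""


class UnknownTissueError(CvAtlasError):
    """A tissue label is not part of the atlas tissue set."""


class DegenerateInputError(CvAtlasError):
    """An operation received input on which its result is undefined."""


class PipelineError(CvAtlasError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
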
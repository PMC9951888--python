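"""Exception hierarchy shared across the pipeline.

Exit-code contract used by the CLI: validation problems exit 2, stage
failures exit 3 (see :mod:`stentmorph.cli`).
"""


class StentMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(StentMorphError):
    """Invalid parameters, malformed input files, or contract violations."""


class StageError(StentMorphError):
    """A pipeline stage failed on otherwise valid input.

    Carries optional case/timepoint context so orchestrated runs can name
    the offending stage.
    """

    def __init__(self, message: str, *, stage: str | None = None,
                 case_id: str | None = None, timepoint: str | None = None):
        self.stage = stage
        self.case_id = case_id
        self.timepoint = timepoint
        prefix = "/".join(x for x in (case_id, timepoint, stage) if x)
        super().__init__(f"[{prefix}] {message}" if prefix else message)
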
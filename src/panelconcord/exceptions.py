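"""Exception hierarchy for panelconcord.

All package errors derive from :class:`PanelConcordError` so callers can
catch everything the pipeline may raise with a single except clause.
"""


class PanelConcordError(Exception):
    """Base class for all panelconcord errors."""


class ConfigurationError(PanelConcordError, ValueError):
    """A configuration object failed validation; the message names the field."""


class FormatError(PanelConcordError, ValueError):
    """A file did not conform to the expected tabular dialect."""


class ParameterError(PanelConcordError, ValueError):
    """An operation received an out-of-range parameter."""


class ConsistencyError(PanelConcordError, ValueError):
    """Inputs that must agree (e.g. manifest vs matrix probe ids) do not."""


class AmbiguityError(PanelConcordError, ValueError):
    """A cross-panel gene match could not be resolved one-to-one."""


class StageError(PanelConcordError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
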
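"""Exception hierarchy for raretrials."""


class RareTrialsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RareTrialsError):
    """A specification or config file field is invalid; message names the field."""


class RecruitmentError(RareTrialsError):
    """Too few eligible patients to run a cohort draw or a design stage."""

    def __init__(self, message: str, n_eligible: int | None = None, n_required: int | None = None):
        super().__init__(message)
        self.n_eligible = n_eligible
        self.n_required = n_required


class StructuralError(RareTrialsError):
    """Mismatched lengths or malformed trial structures."""
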
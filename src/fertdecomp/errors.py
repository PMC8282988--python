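"""Package exception types."""


class FertdecompError(Exception):
    """Base class for package errors."""


class ParameterError(FertdecompError):
    """Invalid simulation or estimation parameters."""


class SchemaError(FertdecompError):
    """Input table does not match the expected column schema."""


class EstimationError(FertdecompError):
    """An estimator was asked for an undefined quantity (e.g. zero exposure)."""


class ClassificationError(FertdecompError):
    """A respondent record lacks a field required for classification."""
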
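"""Exception hierarchy shared across the package."""


class CardioclassError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CardioclassError):
    """A table or model does not conform to the expected feature schema."""


class ValidationError(CardioclassError):
    """Input data violate a structural invariant (duplicates, bad labels...)."""


class StratificationError(CardioclassError):
    """A class is too small for the requested stratified split or folding."""


class UsageError(CardioclassError):
    """An operation was called with inconsistent or unsupported arguments."""


class DomainError(CardioclassError):
    """A numeric argument lies outside its mathematical domain."""


class ModelLoadError(CardioclassError):
    """A serialized model file is missing, truncated, or incompatible."""


class PipelineError(CardioclassError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage
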
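"""Exception hierarchy shared across the package."""


class ConfigurationError(ValueError):
    """A physical or optical parameter is invalid (non-positive length, gain, ...)."""


class ParameterError(ValueError):
    """An analysis parameter is out of its valid range."""


class SchemaError(ConfigurationError):
    """A configuration mapping is missing required keys; lists all of them at once."""

    def __init__(self, missing_keys):
        self.missing_keys = sorted(missing_keys)
        super().__init__(f"missing configuration keys: {', '.join(self.missing_keys)}")


class FormatError(ValueError):
    """An input file is not in the expected format."""


class EstimationError(RuntimeError):
    """An estimator could not produce a reliable value from the data given."""


class ConvergenceError(EstimationError):
    """An iterative procedure failed to converge within its iteration budget."""
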
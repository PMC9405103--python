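"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a scenario or generator is configured outside its valid domain."""


class DataError(ValueError):
    """Raised when input data violate a stage's preconditions (too few records,
    singular covariance, mismatched grids, ...)."""
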
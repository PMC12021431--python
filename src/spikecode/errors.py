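"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A structurally invalid configuration (unknown family, bad layer sizes...)."""


class ValidationError(ValueError):
    """Invalid runtime inputs (shape mismatch, non-positive duration...)."""


class TrainingError(RuntimeError):
    """Optimization diverged (NaN/inf loss)."""
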
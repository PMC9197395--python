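"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An unknown model, phase, order or otherwise invalid configuration."""


class ParameterError(ValueError):
    """Parameter vector inconsistent with the requested model."""


class InputError(ValueError):
    """Input data unusable for the requested operation."""
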
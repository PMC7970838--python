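"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration object violates its contract (bad fractions, paths, ...)."""


class DataError(ValueError):
    """An input record is unusable (zero droplets, nonpositive weight, ...)."""
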
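"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or method parameter violates its constraints."""


class FormatError(ValueError):
    """An on-disk matrix or config file is malformed."""
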
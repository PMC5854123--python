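"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its valid range or non-finite."""


class InputError(ValueError):
    """Input data are missing, malformed, or mutually inconsistent."""


class UndefinedResultError(ValueError):
    """The requested quantity is mathematically undefined for these inputs
    (e.g. an inter-marker distance with fewer than two markers)."""
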
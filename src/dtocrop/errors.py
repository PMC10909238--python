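"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is structurally invalid (e.g. bounds that make a stage impossible)."""


class ContractViolation(ValueError):
    """An input violates a documented call contract (shape, range, finiteness)."""


class RegistrationError(ValueError):
    """Duplicate or unknown name in a plugin registry."""
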
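"""Exception hierarchy for gmhcrf."""


class GMHCRFError(Exception):
    """Base class for all package errors."""


class InputError(GMHCRFError, ValueError):
    """Malformed or inconsistent user-supplied input (data, config, CLI)."""


class ModelValidityError(GMHCRFError, ValueError):
    """A parameter object violates a model invariant (e.g. non-SPD covariance)."""


class InternalConsistencyError(GMHCRFError, RuntimeError):
    """Cached intermediate results disagree with each other beyond tolerance."""
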
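"""Exception hierarchy for the stereology pipeline."""


class WoundStereoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WoundStereoError, ValueError):
    """A scalar input violates its precondition (non-positive length, bad count...)."""


class ConfigurationError(WoundStereoError):
    """A probe or grid cannot be laid out under the requested geometry."""


class SamplingError(WoundStereoError):
    """A sampling field or probe falls outside the available image/wound extent."""


class GenerationError(WoundStereoError):
    """The synthetic-tissue generator could not reach the requested density."""


class SectioningError(WoundStereoError):
    """A section plane lies outside the tissue box."""


class EstimationError(WoundStereoError):
    """No usable counts were available to form an estimate."""
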
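"""Exception hierarchy for cmquant."""


class CmquantError(Exception):
    """Base class for all cmquant errors."""


class InvalidProtocolError(CmquantError):
    """A stimulation protocol violates its invariants (e.g. non-positive
    sampling rate or duration, inverted voltage range)."""


class InvalidTargetError(CmquantError):
    """Generator targets are inconsistent (e.g. APD30 >= APD50)."""


class OverlappingTransientError(CmquantError):
    """Pacing period is too short for the requested transient kernel."""


class UndersampledImageError(CmquantError):
    """Pixel size too coarse to resolve the requested striation period."""


class NoReversalError(CmquantError):
    """An I-V curve has no zero crossing on its positive-voltage limb."""


class DegenerateDataError(CmquantError):
    """Input carries no usable signal (all-zero currents, flat trace, ...)."""


class FitFailureError(CmquantError):
    """A least-squares fit failed to converge; diagnostics in ``args``."""


class NoAPError(CmquantError):
    """No beat window contained a detectable action potential."""


class InsufficientDataError(CmquantError):
    """Fewer complete segments/windows than the operation requires."""


class ProfileError(CmquantError):
    """Line-profile extraction or extremum detection failed."""


class ConfigError(CmquantError):
    """Invalid run configuration or file sidecar."""
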
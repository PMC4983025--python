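"""Exception hierarchy shared across the package."""


class PMPotencyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PMPotencyError):
    """A scenario/panel/design configuration is internally inconsistent."""


class DesignMismatchError(ConfigurationError):
    """A particle panel does not cover the endpoints of the study design."""


class MissingControlsError(PMPotencyError):
    """An experiment has no usable dose-0 records for an endpoint."""

    def __init__(self, experiment, unit=None, endpoint=None, message=None):
        self.experiment = experiment
        self.unit = unit
        self.endpoint = endpoint
        if message is None:
            message = (
                f"no usable dose-0 control records in experiment {experiment!r}"
                + (f" for endpoint {unit!r}/{endpoint!r}" if endpoint else "")
            )
        super().__init__(message)


class InsufficientDataError(PMPotencyError):
    """Too few usable observations to produce a finite estimate.

    Carries the offending (particle, unit, endpoint) key so batch callers
    can report which series failed rather than a bare message.
    """

    def __init__(self, particle=None, unit=None, endpoint=None, message=None):
        self.particle = particle
        self.unit = unit
        self.endpoint = endpoint
        if message is None:
            message = (
                "insufficient data for potency fit: "
                f"particle={particle!r} unit={unit!r} endpoint={endpoint!r}"
            )
        super().__init__(message)


class JoinError(PMPotencyError):
    """Two estimates that must refer to the same particle/unit do not."""


class ValidationError(PMPotencyError):
    """An input table violates the expected schema or contracts."""
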
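"""Exception hierarchy for medloc."""


class MedlocError(Exception):
    """Base class for all medloc errors."""


class InputError(MedlocError):
    """Invalid or inconsistent user-supplied data."""


class ConfigurationError(MedlocError):
    """Invalid model configuration (speed tables, multipliers, ...)."""


class ScheduleError(MedlocError):
    """Invalid annealing schedule."""


class GenerationError(MedlocError):
    """Synthetic instance generation could not satisfy its constraints."""
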
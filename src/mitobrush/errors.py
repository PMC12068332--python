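"""Exception hierarchy.

All user-facing errors derive from :class:`MitobrushError` so callers can
catch one base class; subclasses distinguish configuration problems from
runtime (packing / integration) failures.
"""


class MitobrushError(Exception):
    """Base class for all package errors."""


class ConfigError(MitobrushError, ValueError):
    """Invalid configuration value or combination of values."""


class ValidationError(ConfigError):
    """Aggregated configuration-file validation failure.

    Collects every problem found in a config file so the user can fix them
    in one pass.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        msg = "configuration invalid:\n" + "\n".join(f"  - {p}" for p in self.problems)
        super().__init__(msg)


class PackingError(MitobrushError, RuntimeError):
    """Particles could not be placed (box too small, rejection cap hit)."""


class IntegrationError(MitobrushError, RuntimeError):
    """Langevin integration failed (NaN, overflow, bond over-extension)."""


class AnalysisError(MitobrushError, ValueError):
    """Invalid input to an observable computation."""


class TrajectoryFormatError(MitobrushError, ValueError):
    """Malformed trajectory file."""
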
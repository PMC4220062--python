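"""Exception hierarchy.

Everything raised deliberately by rhythmboot derives from
:class:`RhythmbootError`, so callers can catch the package's own failures
without swallowing genuine bugs.
"""


class RhythmbootError(Exception):
    """Base class for all rhythmboot errors."""


class ConfigurationError(RhythmbootError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputError(RhythmbootError, ValueError):
    """Invalid data passed to a numerical operation."""


class AssemblyError(RhythmbootError, ValueError):
    """Replicate-dataset assembly is impossible (e.g. too few individuals)."""


class SimulationError(RhythmbootError, RuntimeError):
    """A simulation stage failed (e.g. the oscillator never settled)."""


class FormatError(RhythmbootError, ValueError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
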
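"""Exception hierarchy shared across the package."""


class Cas13ScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(Cas13ScreenError):
    """Sequence contains characters outside the A/C/G/T alphabet."""


class MissingDataError(Cas13ScreenError):
    """A required score or record is absent (e.g. uniqueness positions)."""


class ManifestError(Cas13ScreenError):
    """Design manifest violates a structural invariant (e.g. duplicate spacers)."""


class DesignError(Cas13ScreenError):
    """Guide design could not satisfy its inputs."""


class ParseError(Cas13ScreenError):
    """Malformed input record; message carries the record/line index."""


class LibraryFailedError(Cas13ScreenError):
    """A sequencing library is unusable (e.g. all-zero counts)."""


class PairingError(Cas13ScreenError):
    """+Dox/−Dox libraries cannot be matched one-to-one."""


class PopulationExtinctError(Cas13ScreenError):
    """Simulated cell population went extinct; use a larger population."""
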
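"""Exception hierarchy.

``BiofetError`` is the common base; configuration-type failures derive from
``ConfigurationError`` so shell entry points can map them to a distinct exit
code from data-quality failures.
"""


class BiofetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BiofetError, ValueError):
    """A physical parameter is out of its admissible range."""


class ExtractionError(BiofetError):
    """No fit window met the figure-of-merit extraction criteria."""


class DataConventionError(BiofetError, ValueError):
    """Input data violate the stated sign/units convention."""


class PairingError(BiofetError):
    """Baseline and signal curves could not be matched one-to-one."""


class InsufficientReplicatesError(BiofetError):
    """Fewer replicates than a statistical operation requires."""


class SelectionError(BiofetError):
    """An atom/group selection resolved to nothing."""


class SuperpositionError(BiofetError):
    """Rigid-body superposition is undefined for the given coordinates."""


class EmptyAnalysisError(BiofetError):
    """No frames left to analyse (e.g. equilibration trim too aggressive)."""


class ConfigurationError(BiofetError):
    """Required configuration (charges, paths, modes) is missing or invalid."""


class SpecError(ConfigurationError):
    """A synthetic-data generation spec is infeasible."""
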
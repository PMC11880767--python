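"""Exception hierarchy.

Every error raised by the library derives from :class:`KcatError`, so callers
(and the CLI) can separate data/validation problems from genuine bugs.
"""


class KcatError(Exception):
    """Base class for all kcatnet errors."""


class FormatError(KcatError):
    """A dataset file is malformed (e.g. a required column is missing)."""


class EmptyDatasetError(KcatError):
    """A dataset file contains no usable rows."""


class SplitError(KcatError):
    """Train/validation/test splitting is impossible or misconfigured."""


class StratificationError(KcatError):
    """Similarity stratification cannot be performed (e.g. empty train set)."""


class StructureParseError(KcatError):
    """A structure file could not be parsed into a Cα trace."""


class EmptyStructureError(StructureParseError):
    """A parsed chain contains no residue with a Cα atom."""


class TokenizationError(KcatError):
    """A sequence is too short for the configured n-gram size."""


class ChemistryParseError(KcatError):
    """A SMILES string could not be parsed."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class ShapeError(KcatError):
    """Array dimensions are inconsistent."""


class ConfigError(KcatError):
    """A model or training configuration value is invalid."""


class GraphError(KcatError):
    """An adjacency matrix violates the graph contract (symmetry, etc.)."""


class FusionError(KcatError):
    """Attention fusion received an empty or inconsistent input."""


class InputError(KcatError):
    """Record-level features are inconsistent (e.g. sequence/structure length)."""


class TrainingError(KcatError):
    """Training diverged or could not run."""


class StatisticsError(KcatError):
    """A statistical test is undefined for the given inputs."""


class AnnotationError(KcatError):
    """A site annotation is empty or out of range."""
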
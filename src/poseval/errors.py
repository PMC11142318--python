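"""Exception hierarchy for pose evaluation.

Scoring-stage errors deliberately subclass :class:`ScoringError` so the
evaluation driver can convert them into ``excluded`` statuses rather than
crashing a batch run.
"""


class PosevalError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PosevalError):
    """A structure or molecule file failed to parse."""


class ScoringError(PosevalError):
    """Base for errors that exclude a prediction from evaluation."""


class MissingPrimaryError(ScoringError):
    """No predicted fragment matches the reference primary ligand graph."""


class GraphMismatchError(ScoringError):
    """Two ligands expected to share a molecular graph do not."""


class DegenerateAlignmentError(ScoringError):
    """Too few or rank-deficient points for a rigid superposition."""


class MissingPocketResiduesError(DegenerateAlignmentError):
    """Pocket residues absent from the mobile structure."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "pocket residues missing from mobile structure: "
            + ", ".join(f"{c}/{i}" for c, i in self.missing)
        )


class ChainMappingError(ScoringError):
    """No sequence-compatible chain bijection exists."""


class UndefinedScoreError(ScoringError):
    """A score has an empty support (no neighbours / no contacts)."""


class EmptyHistogramsError(ScoringError):
    """A Wasserstein distance was requested on empty histograms."""
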
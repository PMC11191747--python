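"""Exception hierarchy for porenet.

All porenet-specific failures derive from :class:`PorenetError` so callers can
catch one base class at the CLI boundary.
"""


class PorenetError(Exception):
    """Base class for all porenet errors."""


class InputError(PorenetError):
    """A file or in-memory input failed to parse or violated a precondition."""


class ClassificationError(InputError):
    """One or more residue names could not be assigned a molecule class."""

    def __init__(self, residue_names):
        self.residue_names = sorted(set(residue_names))
        super().__init__(
            "unclassifiable residue name(s): " + ", ".join(self.residue_names)
        )


class TopologyError(PorenetError):
    """The topology is internally inconsistent (e.g. an orphan hydrogen)."""


class RangeError(PorenetError):
    """A requested analysis window falls outside the trajectory."""


class StrideError(PorenetError):
    """A requested stride is not a multiple of the trajectory saving interval."""


class ParameterError(PorenetError):
    """A numeric parameter is out of its admissible range."""


class ControlError(PorenetError):
    """Assay control readings are degenerate (positive == negative)."""


class FitError(PorenetError):
    """A nonlinear fit failed to converge."""


class GenerationError(PorenetError):
    """The synthetic pore builder was handed an infeasible geometry."""


class SequenceError(PorenetError):
    """A peptide sequence contains a nonstandard one-letter code."""


class ConfigurationError(PorenetError):
    """An unknown named option (e.g. hydropathy scale) was requested."""
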
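"""Exception hierarchy shared across the package."""


class InvfoldError(Exception):
    """Base class for all package-specific errors."""


class FormatError(InvfoldError):
    """A structure or sequence file could not be parsed."""


class EmptyStructureError(InvfoldError):
    """No usable protein residues were found."""


class DegenerateGeometryError(InvfoldError):
    """Coordinates do not define the requested geometric construction."""


class GeometryError(InvfoldError):
    """Generated or assembled coordinates are physically inconsistent."""


class UndefinedMetricError(InvfoldError):
    """A structural metric is undefined for this input (e.g. too few residues)."""


class ConstraintError(InvfoldError):
    """Design constraints are inconsistent with each other or the structure."""


class ConfigurationError(InvfoldError):
    """Model configuration and inputs disagree in shape or vocabulary."""


class TrainingDivergedError(InvfoldError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch
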
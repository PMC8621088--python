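"""Exception hierarchy shared across the pipeline stages."""


class HainiError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(HainiError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class DimensionError(HainiError):
    """Vector or matrix dimensions do not match the declared contract."""


class SchemaError(HainiError):
    """A table, profile or feature matrix violates the declared schema."""


class CYPConflictError(HainiError):
    """A drug is declared both inhibitor and inducer of the same enzyme."""


class SelectionError(HainiError):
    """Feature selection was asked for more than it can deliver."""


class SplitError(HainiError):
    """A stratified split cannot be formed (e.g. singleton classes)."""


class SimulationError(HainiError):
    """Synthetic data generation request is infeasible."""


class ConfigError(HainiError):
    """Pipeline configuration is missing or invalid."""
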
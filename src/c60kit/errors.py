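"""Exception types shared across the toolkit."""


class C60KitError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(C60KitError, ValueError):
    """A scalar parameter is outside its physical/valid range."""


class InvalidInputError(C60KitError, ValueError):
    """Structured input (arrays, lists, systems) is malformed."""


class UnsupportedSymmetryError(C60KitError, ValueError):
    """Space-group symbol not recognised."""


class IncompleteResidueError(C60KitError, KeyError):
    """A residue lacks one of the required backbone atoms."""

    def __init__(self, chain_id: str, residue_index: int, atom_name: str):
        self.chain_id = chain_id
        self.residue_index = residue_index
        self.atom_name = atom_name
        super().__init__(
            f"residue {chain_id}/{residue_index} is missing backbone atom {atom_name!r}"
        )


class InsufficientDataError(C60KitError, ValueError):
    """Not enough data points / samples / species to proceed."""


class ConfigurationError(C60KitError, ValueError):
    """Inconsistent run configuration (schedule vs system, missing step...)."""
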
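"""Exception hierarchy for the allosite package."""


class AllositeError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(AllositeError):
    """A PDB ATOM/HETATM record could not be parsed (message names the line)."""


class EmptyInputError(AllositeError):
    """An input that must contain data (atoms, scores, points) was empty."""


class AlignmentError(AllositeError):
    """Malformed multiple sequence alignment (ragged rows, too few records)."""


class MappingError(AllositeError):
    """A site residue could not be located in the aligned reference sequence."""


class GridError(AllositeError):
    """Invalid density-grid geometry or non-finite values on write."""


class GridMismatchError(GridError):
    """Two grids that must be congruent (origin/dims/spacing) are not."""


class DegenerateGeometryError(AllositeError):
    """Point set too degenerate (collinear / too few points) for superposition."""


class RosterMismatchError(AllositeError):
    """Atom rosters of two structures expected to match do not."""
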
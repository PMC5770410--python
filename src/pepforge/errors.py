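"""Exception types shared across the package."""


class PepforgeError(Exception):
    """Base class for package errors."""


class SelectionError(PepforgeError):
    """A chain/residue/atom selection could not be satisfied."""


class FragmentationError(PepforgeError):
    """A requested cut would not partition the molecular graph."""


class GeometryError(PepforgeError):
    """Degenerate geometry (collinear dihedral points, empty box, ...)."""


class ConformationError(PepforgeError):
    """A conformation state is incomplete or out of a torsion's range."""
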
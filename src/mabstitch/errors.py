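"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`MabstitchError`
so pipeline drivers can catch one type and report the failing stage.
"""


class MabstitchError(Exception):
    """Base class for all package errors."""


class ChemistryError(MabstitchError):
    """Unknown element, residue or monomer code."""


class FormatError(MabstitchError):
    """Unparseable or unwritable file content."""


class GeometryError(MabstitchError):
    """Degenerate or invalid geometric input (collinear points, too few atoms)."""


class TopologyError(MabstitchError):
    """Inconsistent covalent topology (missing template atom, bad link)."""


class ScriptError(MabstitchError):
    """An edit-script operation references a residue that does not exist."""


class SpliceError(MabstitchError):
    """Splice junction is missing backbone atoms or is otherwise unusable."""


class AssemblyError(MabstitchError):
    """Parts are incompatible at a junction (RMSD gate exceeded, bad plan)."""


class SymmetryError(MabstitchError):
    """A claimed two-fold axis is not close to a 180 degree rotation."""


class MinimizationError(MabstitchError):
    """Non-finite energy encountered during minimization."""


class SelectionError(MabstitchError):
    """An atom/residue selection matched nothing."""


class CapacityError(MabstitchError):
    """Output format cannot hold the model (e.g. >99999 atoms in PDB)."""
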
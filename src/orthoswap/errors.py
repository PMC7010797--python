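"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`OrthoswapError`, so callers (notably the CLI) can separate user-input
problems from genuine bugs.
"""


class OrthoswapError(Exception):
    """Base class for all orthoswap errors."""


class SequenceFormatError(OrthoswapError, ValueError):
    """Malformed FASTA input or an invalid residue string."""


class AlignmentError(OrthoswapError, ValueError):
    """Invalid alignment parameters or substitution matrix."""


class TargetSpecError(OrthoswapError, ValueError):
    """A target-position specification that violates its invariants."""


class DesignError(OrthoswapError, ValueError):
    """A design-stage contract violation (empty database, bad substitution)."""


class StructureError(OrthoswapError, ValueError):
    """Problems reading coordinates or locating chains/residues."""


class ClusterSpecError(OrthoswapError, ValueError):
    """Malformed cluster string such as ``"140,470;;484"``."""


class SynthesisError(OrthoswapError, ValueError):
    """Infeasible synthetic-homolog request."""
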
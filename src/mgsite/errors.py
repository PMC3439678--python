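"""Exception hierarchy for the annotation-transfer pipeline."""


class MgsiteError(Exception):
    """Base class for all package errors."""


class PdbFormatError(MgsiteError):
    """A PDB record violates the fixed-column format."""


class EmptyStructureError(MgsiteError):
    """Coordinate file carries no ATOM/HETATM records."""


class MappingError(MgsiteError):
    """Residue-mapping file is malformed or non-injective."""


class InvalidReferenceError(MgsiteError):
    """Reference (mature) sequence is empty or inconsistent."""


class MembershipError(MgsiteError):
    """Target sequence is not a member of the cluster."""


class NotTransferableError(MgsiteError):
    """A template site residue cannot be carried through the HMM."""


class OntologyError(MgsiteError):
    """Ontology edge list is cyclic or otherwise not a rooted DAG."""


class FixtureError(MgsiteError):
    """Synthetic-fixture generation failed (degenerate parameters)."""
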
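"""Synthetic protein families and toy PDB structures for self-contained runs.

The generator emulates the pipeline's real-world inputs at desk scale: a
protein family is derived from a root sequence by i.i.d. substitutions and
geometric-length indels (with a per-member truth table tracking where each
planted binding position lands), and a toy PDB file renders a member as a
CA-trace helix with magnesium ions, coordinating oxygen atoms, and
column-correct LINK / SITE / REMARK 800 records — including, on request,
an extra ion coordinated only by water, the case the extraction stage must
recognise and set aside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FixtureError
from .seqmap import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# residues able to offer a side-chain oxygen, weighted toward Asp/Glu as in
# observed magnesium coordination spheres
_BINDING_POOL = "DDDEEENQST"

# side-chain oxygen atom used for a coordinating residue
SIDECHAIN_O = {"D": "OD1", "E": "OE1", "N": "OD1", "Q": "OE1",
               "S": "OG", "T": "OG1", "Y": "OH"}

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated protein family."""

    root: str | None = None
    root_length: int = 90
    family_size: int = 6
    substitution_rate: float = 0.10
    indel_rate: float = 0.01
    indel_length_p: float = 0.5  # geometric length parameter
    binding_positions: tuple = (12, 30, 55, 70)
    seed: int = 0
    prefix: str = "FAM"

    def __post_init__(self):
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        n = len(self.root) if self.root else self.root_length
        if any(not (1 <= p <= n) for p in self.binding_positions):
            raise ValueError("binding positions must lie within the root sequence")


def draw_root(length: int, binding_positions, rng) -> str:
    """Random root sequence with oxygen-bearing residues at planted sites."""
    letters = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    for p in binding_positions:
        letters[p - 1] = _BINDING_POOL[rng.integers(0, len(_BINDING_POOL))]
    return "".join(letters)


def derive_member(sequence: str, rng, substitution_rate: float,
                  indel_rate: float, indel_length_p: float = 0.5):
    """One mutated descendant plus the position map parent -> child.

    The map sends each 1-based parent position to its child position or
    the string "deleted".
    """
    out: list[str] = []
    mapping: dict[int, object] = {}
    n = len(sequence)
    i = 1
    while i <= n:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(indel_length_p))
            if rng.random() < 0.5:  # insertion before position i
                out.extend(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))
            else:  # deletion of `length` parent positions
                for j in range(i, min(i + length, n + 1)):
                    mapping[j] = "deleted"
                i += length
                continue
        ch = sequence[i - 1]
        if substitution_rate > 0 and rng.random() < substitution_rate:
            alternatives = AMINO_ACIDS.replace(ch, "")
            ch = alternatives[rng.integers(0, len(alternatives))]
        out.append(ch)
        mapping[i] = len(out)
        i += 1
    if not out:
        raise FixtureError("mutation rates emptied the member sequence")
    return "".join(out), mapping


def generate_family(spec: FamilySpec):
    """Simulate one family and its binding-position truth table.

    Returns (records, truth): the first record (accession ``<prefix>T``)
    is the unmutated root/template; truth maps each member accession to
    ``{root binding position: member position | "deleted"}``.  Output is
    deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    root = spec.root or draw_root(spec.root_length, spec.binding_positions, rng)
    records = [SequenceRecord(f"{spec.prefix}T", root, organism="synthetic")]
    truth = {f"{spec.prefix}T": {p: p for p in spec.binding_positions}}
    for m in range(1, spec.family_size):
        seq, mapping = derive_member(root, rng, spec.substitution_rate,
                                     spec.indel_rate, spec.indel_length_p)
        acc = f"{spec.prefix}M{m:02d}"
        records.append(SequenceRecord(acc, seq, organism="synthetic"))
        truth[acc] = {p: mapping[p] for p in spec.binding_positions}
    return records, truth


def generate_divergent_chain(spec: FamilySpec, n_steps: int = 5):
    """A chain root -> m1 -> ... -> m_k of successively mutated sequences.

    Each step applies the spec's rates to the previous member, so the last
    member is far from the root (useful for sub-30%-identity transfer
    tests) while adjacent members stay similar enough to keep the family
    in one graph component.  Truth maps are composed along the chain.
    """
    rng = np.random.default_rng(spec.seed)
    root = spec.root or draw_root(spec.root_length, spec.binding_positions, rng)
    records = [SequenceRecord(f"{spec.prefix}T", root, organism="synthetic")]
    truth = {f"{spec.prefix}T": {p: p for p in spec.binding_positions}}
    current, cum = root, {p: p for p in spec.binding_positions}
    for step in range(1, n_steps + 1):
        current, mapping = derive_member(current, rng, spec.substitution_rate,
                                         spec.indel_rate, spec.indel_length_p)
        cum = {p: (mapping[v] if v != "deleted" else "deleted")
               for p, v in cum.items()}
        acc = f"{spec.prefix}M{step:02d}"
        records.append(SequenceRecord(acc, current, organism="synthetic"))
        truth[acc] = dict(cum)
    return records, truth


def _helix_ca(index: int) -> np.ndarray:
    """CA position of residue `index` (1-based) on an ideal helix trace."""
    theta = np.deg2rad(100.0) * (index - 1)
    return np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * (index - 1)])


def _atom_name_field(name: str) -> str:
    """PDB columns 13-16: element-aligned atom name."""
    if len(name) >= 4:
        return name[:4]
    if name in ("MG",):  # two-letter element symbols start at column 13
        return f"{name:<4}"
    return f" {name:<3}"


def _atom_line(serial, name, resname, chain, resnum, xyz, hetatm=False,
               element=None) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    element = element or name[0]
    return (f"{record}{serial:>5} {_atom_name_field(name)} {resname:>3} "
            f"{chain}{resnum:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def _link_line(atom1, res1, chain1, num1, atom2, res2, chain2, num2,
               distance) -> str:
    return (f"LINK        {_atom_name_field(atom1)} {res1:>3} {chain1}{num1:>4}"
            f"                {_atom_name_field(atom2)} {res2:>3} {chain2}{num2:>4}"
            f"   {'1555':>6} {'1555':>6} {distance:5.2f}")


def _site_lines(site_id: str, residues, chain: str) -> list[str]:
    lines = []
    for block_no, start in enumerate(range(0, len(residues), 4), start=1):
        chunk = residues[start:start + 4]
        fields = []
        for resname, resnum in chunk:
            fields.append(f"{resname:>3} {chain}{resnum:>4}  ")
        line = (f"SITE   {block_no:>3} {site_id:<3} {len(residues):>2} "
                + "".join(fields))
        lines.append(line.rstrip())
    return lines


def write_toy_pdb(sequence: str, binding_positions, n_metals: int = 1,
                  include_water_only_site: bool = False, seed: int = 0,
                  author_offset: int = 0, pdb_id: str = "TOY1",
                  chain: str = "A", site_groups=None,
                  coord_noise: float = 0.0):
    """Render a member sequence as a toy PDB file with MG coordination.

    The chain is written as a CA trace on an ideal helix; the binding
    positions are shared round-robin among ``n_metals`` magnesium ions,
    each placed 2.1 angstrom from the coordinating oxygen atoms it binds.
    LINK records assert every contact and each ion gets a SITE block with
    a REMARK 800 description.  With ``include_water_only_site`` an extra
    ion coordinated only by two waters is added.  ``site_groups`` fixes an
    explicit partition of the binding positions over the metals (overrides
    the default round-robin split); ``coord_noise`` adds seeded Gaussian
    jitter (angstrom) to the CA trace, giving distinct but superposable
    copies of one fold.  Returns (pdb text, mapping TSV text); the mapping
    is the identity shifted by ``author_offset``.
    """
    n = len(sequence)
    positions = sorted(set(binding_positions))
    if any(not (1 <= p <= n) for p in positions):
        raise FixtureError("binding positions outside the sequence")
    if n_metals < 1:
        raise FixtureError("need at least one metal")
    if positions and n_metals > len(positions):
        raise FixtureError("more metals than binding positions")

    if site_groups is not None:
        groups = [sorted(g) for g in site_groups]
        if sorted(p for g in groups for p in g) != positions or \
                len(groups) != n_metals:
            raise FixtureError("site_groups must partition the binding positions")
    else:
        groups = [positions[i::n_metals] for i in range(n_metals)]
    author = {p: p + author_offset for p in range(1, n + 1)}

    rng = np.random.default_rng(seed)
    atoms, links, remarks, site_blocks = [], [], [], []
    serial = 1
    ca = {p: _helix_ca(p) + (rng.normal(0.0, coord_noise, size=3)
                             if coord_noise > 0 else 0.0)
          for p in range(1, n + 1)}
    for p in range(1, n + 1):
        resname = AA1_TO_3[sequence[p - 1]]
        atoms.append(_atom_line(serial, "CA", resname, chain, author[p], ca[p]))
        serial += 1
        atoms.append(_atom_line(serial, "O", resname, chain, author[p],
                                ca[p] + np.array([0.6, 0.6, 0.9])))
        serial += 1

    metal_resnum = 301
    water_resnum = 401
    hetatms = []
    site_no = 0
    for gi, group in enumerate(groups):
        site_no += 1
        site_id = f"AC{site_no}"
        centroid = np.mean([ca[p] for p in group], axis=0)
        radial = centroid - np.array([0.0, 0.0, centroid[2]])
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        metal_xyz = centroid + 4.0 * direction + np.array([0.0, 0.0, 0.17 * gi])
        site_residues = []
        for p in group:
            letter = sequence[p - 1]
            resname = AA1_TO_3[letter]
            atom = SIDECHAIN_O.get(letter, "O")
            towards = ca[p] - metal_xyz
            o_xyz = metal_xyz + 2.1 * towards / np.linalg.norm(towards)
            if atom != "O":  # backbone O was already written
                atoms.append(_atom_line(serial, atom, resname, chain,
                                        author[p], o_xyz))
                serial += 1
            links.append(_link_line("MG", "MG", chain, metal_resnum,
                                    atom, resname, chain, author[p], 2.10))
            site_residues.append((resname, author[p]))
        hetatms.append(_atom_line(serial, "MG", "MG", chain, metal_resnum,
                                  metal_xyz, hetatm=True, element="MG"))
        serial += 1
        remarks += [
            "REMARK 800",
            f"REMARK 800 SITE_IDENTIFIER: {site_id}",
            "REMARK 800 EVIDENCE_CODE: SOFTWARE",
            f"REMARK 800 SITE_DESCRIPTION: BINDING SITE FOR RESIDUE MG "
            f"{chain} {metal_resnum}",
        ]
        site_blocks += _site_lines(site_id, site_residues, chain)
        metal_resnum += 1

    if include_water_only_site:
        site_no += 1
        site_id = f"AC{site_no}"
        base = _helix_ca(n) + np.array([8.0, 0.0, 4.0])
        hetatms.append(_atom_line(serial, "MG", "MG", chain, metal_resnum,
                                  base, hetatm=True, element="MG"))
        serial += 1
        site_residues = []
        for w in range(2):
            w_xyz = base + 2.1 * np.array([np.cos(w * 2.1), np.sin(w * 2.1), 0.3])
            hetatms.append(_atom_line(serial, "O", "HOH", chain,
                                      water_resnum, w_xyz, hetatm=True, element="O"))
            serial += 1
            links.append(_link_line("MG", "MG", chain, metal_resnum,
                                    "O", "HOH", chain, water_resnum, 2.10))
            site_residues.append(("HOH", water_resnum))
            water_resnum += 1
        remarks += [
            "REMARK 800",
            f"REMARK 800 SITE_IDENTIFIER: {site_id}",
            "REMARK 800 EVIDENCE_CODE: SOFTWARE",
            f"REMARK 800 SITE_DESCRIPTION: BINDING SITE FOR RESIDUE MG "
            f"{chain} {metal_resnum}",
        ]
        site_blocks += _site_lines(site_id, site_residues, chain)
        metal_resnum += 1

    header = [
        f"HEADER    SYNTHETIC METAL BINDING                 01-JAN-20   {pdb_id:<4}",
        "TITLE     SYNTHETIC CA-TRACE FIXTURE WITH MAGNESIUM COORDINATION",
        "REMARK   2 RESOLUTION.    2.00 ANGSTROMS.",
    ]
    body = header + remarks + site_blocks + links + atoms + hetatms + ["END"]
    pdb_text = "\n".join(body) + "\n"

    mapping_lines = ["pdb_id\tchain\tauthor_number\tins_code\tref_position"]
    for p in range(1, n + 1):
        mapping_lines.append(f"{pdb_id}\t{chain}\t{author[p]}\t\t{p}")
    return pdb_text, "\n".join(mapping_lines) + "\n"


def three_family_records(seed: int = 0, substitution_rate: float = 0.05,
                         family_size: int = 5, root_length: int = 90):
    """Three unrelated families; the first carries the structural template.

    Returns (records, truth of family A, family assignment dict).
    """
    rng = np.random.default_rng(seed)
    records, assignment = [], {}
    truth_a = None
    for fam, prefix in enumerate(("A", "B", "C")):
        spec = FamilySpec(
            root_length=root_length, family_size=family_size,
            substitution_rate=substitution_rate, indel_rate=0.005,
            binding_positions=(12, 30, 55, 70),
            seed=int(rng.integers(0, 2**31 - 1)), prefix=prefix,
        )
        fam_records, fam_truth = generate_family(spec)
        if fam == 0:
            truth_a = fam_truth
        records.extend(fam_records)
        assignment.update({r.accession: prefix for r in fam_records})
    return records, truth_a, assignment
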
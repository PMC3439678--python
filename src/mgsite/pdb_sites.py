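"""Extraction of metal coordination sites from PDB coordinate files.

Magnesium sites are read from two depositor-annotated record types: LINK
records, which assert individual metal-atom contacts (and carry the atom
name needed to split backbone-carbonyl from side-chain coordination), and
SITE records, whose REMARK 800 descriptions name the bound hetero group.
The two evidence sources are merged per metal instance; water partners are
dropped from the coordination list, and a site whose annotated sphere holds
no protein residue at all is flagged ``water_only`` and excluded from any
downstream transfer.

Parsing is strictly column-driven (PDB 3.x fixed columns), never
whitespace-split.  Only MODEL 1 and altloc ' '/'A' atoms are considered.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStructureError, InvalidReferenceError, PdbFormatError

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

DEFAULT_WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

# hetero codes counted as free ions when labelling co-crystallisation modes
ION_CODES = frozenset({
    "ZN", "CA", "MN", "NA", "K", "FE", "FE2", "CU", "CU1", "NI", "CO",
    "CD", "CL", "BR", "IOD", "F", "LI", "RB", "CS", "SR", "BA", "AL", "HG",
})


@dataclass(frozen=True)
class ResidueRef:
    """One residue as addressed by PDB author numbering."""

    chain: str
    resname: str
    resnum: int
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.resnum, self.icode)


@dataclass(frozen=True)
class CoordinationContact:
    """One metal-to-atom contact asserted by a LINK record."""

    metal_chain: str
    metal_resnum: int
    metal_code: str
    partner: ResidueRef
    partner_atom: str
    distance: float | None
    contact_class: str  # backbone | sidechain | water | other

    @property
    def metal_instance(self) -> tuple[str, int]:
        return (self.metal_chain, self.metal_resnum)


@dataclass
class MetalSite:
    """One metal ion and its protein coordination sphere.

    ``coordinating_positions`` holds (reference position, one-letter code)
    pairs, strictly increasing; water partners never appear there.
    ``contact_classes`` maps reference position to backbone/sidechain/other
    when LINK evidence provides the atom, or "unknown" for SITE-only
    positions.  ``water_only`` is true when the annotated sphere holds no
    protein residue; such sites are excluded from annotation transfer.
    """

    pdb_id: str
    chain: str
    metal_instance: int
    coordinating_positions: list = field(default_factory=list)
    contact_classes: dict = field(default_factory=dict)
    water_only: bool = False
    evidence: str = "LINK"  # LINK | SITE | both
    unmapped: list = field(default_factory=list)


@dataclass
class TemplateStructure:
    """A PDB chain tied to its reference sequence, with its metal sites."""

    pdb_id: str
    chain: str
    accession: str
    observed_positions: set
    coverage: float
    sites: list
    resolution: float | None = None
    binding_mode: str = "Mg"
    role_label: str = "undetermined"  # functional | structural | undetermined

    @property
    def transferable_sites(self) -> list:
        return [s for s in self.sites if not s.water_only]


def classify_contact_atom(residue_name: str, atom_name: str,
                          water_codes=DEFAULT_WATER_CODES) -> str:
    """Class of a coordinating atom: water, backbone, sidechain or other.

    Only the carbonyl/terminal oxygens O and OXT count as backbone —
    magnesium coordinates through oxygen, so the backbone class means
    "backbone carbonyl" here.  Total function: any input gets a class.
    """
    resname = residue_name.strip().upper()
    atom = atom_name.strip().upper()
    if resname in water_codes:
        return "water"
    if resname in STANDARD_AA3:
        return "backbone" if atom in {"O", "OXT"} else "sidechain"
    return "other"


def _coordinate_lines(pdb_text: str):
    """ATOM/HETATM lines of MODEL 1 with altloc ' ' or 'A'."""
    lines, in_model, seen_model = [], True, False
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            if seen_model:
                break
            seen_model, in_model = True, True
            continue
        if rec == "ENDMDL":
            if seen_model:
                break
            continue
        if rec in ("ATOM  ", "HETATM") and in_model:
            if len(line) >= 17 and line[16] not in (" ", "A"):
                continue
            lines.append(line)
    return lines


def _require_coordinates(pdb_text: str) -> None:
    if not any(l[:6] in ("ATOM  ", "HETATM") for l in pdb_text.splitlines()):
        raise EmptyStructureError("no ATOM/HETATM records in coordinate file")


def _parse_link_partner(line: str, offset: int) -> tuple[str, ResidueRef]:
    """Atom/residue halves of a LINK record (offset 12 or 42)."""
    atom = line[offset:offset + 4].strip()
    resname = line[offset + 5:offset + 8].strip()
    chain = line[offset + 9:offset + 10].strip()
    resnum_s = line[offset + 10:offset + 14]
    icode = line[offset + 14:offset + 15].strip()
    if not resnum_s.strip():
        raise PdbFormatError("missing residue number")
    try:
        resnum = int(resnum_s)
    except ValueError as exc:
        raise PdbFormatError(f"bad residue number field {resnum_s!r}") from exc
    if not resname:
        raise PdbFormatError("missing residue name")
    return atom, ResidueRef(chain, resname, resnum, icode)


def parse_coordination_contacts(pdb_text: str, metal_code: str = "MG",
                                water_codes=DEFAULT_WATER_CODES,
                                max_distance: float | None = None,
                                errors: list | None = None) -> list[CoordinationContact]:
    """All LINK contacts in which exactly one partner is the metal.

    The metal may stand on either side of the record; contacts are returned
    in file order.  Malformed LINK lines are collected into ``errors`` (or
    raised as warnings when no list is given) and parsing continues.  A
    distance outside (0, 10) angstrom is rejected as implausible; an extra
    ``max_distance`` cut may tighten that.
    """
    _require_coordinates(pdb_text)
    sink = errors if errors is not None else []
    contacts = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] != "LINK  ":
            continue
        try:
            if len(line) < 57:
                raise PdbFormatError("LINK record too short for fixed columns")
            atom1, res1 = _parse_link_partner(line, 12)
            atom2, res2 = _parse_link_partner(line, 42)
            dist_s = line[73:78].strip()
            distance = float(dist_s) if dist_s else None
        except PdbFormatError as exc:
            sink.append(f"line {lineno}: {exc}")
            continue
        is_metal1 = res1.resname == metal_code
        is_metal2 = res2.resname == metal_code
        if is_metal1 == is_metal2:  # neither, or metal-metal
            continue
        metal, partner, atom = (res1, res2, atom2) if is_metal1 else (res2, res1, atom1)
        if distance is not None and not (0.0 < distance < 10.0):
            sink.append(f"line {lineno}: implausible LINK distance {distance} A")
            continue
        if max_distance is not None and distance is not None and distance > max_distance:
            continue
        contacts.append(CoordinationContact(
            metal_chain=metal.chain,
            metal_resnum=metal.resnum,
            metal_code=metal_code,
            partner=partner,
            partner_atom=atom,
            distance=distance,
            contact_class=classify_contact_atom(partner.resname, atom, water_codes),
        ))
    if errors is None:
        for msg in sink:
            warnings.warn(f"LINK parse: {msg}", stacklevel=2)
    return contacts


_REMARK800_ID = re.compile(r"^REMARK 800 SITE_IDENTIFIER:\s*(\S+)")
_REMARK800_DESC = re.compile(r"^REMARK 800 SITE_DESCRIPTION:\s*(.+?)\s*$")
_METAL_DESC = re.compile(r"RESIDUE\s+(\S+)\s+(\S)\s+(-?\d+)")


def parse_site_records(pdb_text: str, metal_code: str = "MG") -> dict:
    """SITE residues for every site whose REMARK 800 description names the metal.

    Returns ``{(metal chain, metal residue number): [ResidueRef, ...]}``,
    waters included.  Sites whose description names another hetero group
    are ignored; a SITE identifier absent from REMARK 800 is kept but
    reported, since without a description it cannot name the metal.
    """
    _require_coordinates(pdb_text)
    descriptions: dict[str, str] = {}
    current_id = None
    for line in pdb_text.splitlines():
        m = _REMARK800_ID.match(line)
        if m:
            current_id = m.group(1)
            continue
        m = _REMARK800_DESC.match(line)
        if m and current_id is not None:
            descriptions[current_id] = m.group(1)
            current_id = None

    site_residues: dict[str, list[ResidueRef]] = {}
    last_seq: dict[str, int] = {}
    for line in pdb_text.splitlines():
        if line[:6] != "SITE  ":
            continue
        seq_s = line[7:10].strip()
        site_id = line[11:14].strip()
        if not site_id:
            raise PdbFormatError(f"SITE record without identifier: {line!r}")
        seq = int(seq_s) if seq_s else 1
        if site_id in last_seq and seq != last_seq[site_id] + 1:
            raise PdbFormatError(
                f"SITE {site_id}: continuation line {seq} out of order "
                f"(expected {last_seq[site_id] + 1})"
            )
        last_seq[site_id] = seq
        bucket = site_residues.setdefault(site_id, [])
        for start in (18, 29, 40, 51):
            resname = line[start:start + 3].strip()
            if not resname:
                continue
            chain = line[start + 4:start + 5].strip()
            resnum_s = line[start + 5:start + 9]
            icode = line[start + 9:start + 10].strip() if len(line) > start + 9 else ""
            try:
                resnum = int(resnum_s)
            except ValueError as exc:
                raise PdbFormatError(
                    f"SITE {site_id}: bad residue number {resnum_s!r}"
                ) from exc
            bucket.append(ResidueRef(chain, resname, resnum, icode))

    result: dict[tuple[str, int], list] = {}
    for site_id, residues in site_residues.items():
        desc = descriptions.get(site_id)
        if desc is None:
            warnings.warn(
                f"SITE {site_id} has no REMARK 800 description; kept with "
                "unknown description", stacklevel=2)
            continue
        m = _METAL_DESC.search(desc)
        if m and m.group(1) == metal_code:
            result[(m.group(2), int(m.group(3)))] = residues
    return result


def build_metal_sites(contacts, site_map, residue_map,
                      pdb_id: str = "", water_codes=DEFAULT_WATER_CODES,
                      reference=None) -> list[MetalSite]:
    """Merge LINK and SITE evidence into one MetalSite per metal instance.

    Water partners are dropped from the coordination list; a metal whose
    whole annotated sphere is water is flagged ``water_only``.  Protein
    residues are carried into reference numbering through ``residue_map``;
    residues absent from the map are excluded and reported on the site.
    When ``reference`` (a SequenceRecord) is given, residue letters are
    read from it and positions checked against the sequence length.
    """
    per_metal: dict[tuple[str, int], dict] = {}

    def bucket(instance):
        return per_metal.setdefault(
            instance,
            {"residues": {}, "classes": {}, "evidence": set(), "nonwater_other": False},
        )

    for contact in contacts:
        b = bucket(contact.metal_instance)
        b["evidence"].add("LINK")
        res = contact.partner
        if contact.contact_class == "water":
            continue
        b["residues"][(res.chain,) + res.key] = res
        prev = b["classes"].get((res.chain,) + res.key)
        # first atom-level class wins; LINK detail beats SITE's "unknown"
        if prev in (None, "unknown"):
            b["classes"][(res.chain,) + res.key] = contact.contact_class

    for instance, residues in site_map.items():
        b = bucket(instance)
        b["evidence"].add("SITE")
        for res in residues:
            if res.resname.strip().upper() in water_codes:
                continue
            key = (res.chain,) + res.key
            b["residues"].setdefault(key, res)
            b["classes"].setdefault(key, classify_contact_atom(res.resname, "", water_codes)
                                    if res.resname.strip().upper() not in STANDARD_AA3
                                    else "unknown")

    sites = []
    for (chain, resnum), b in sorted(per_metal.items()):
        site = MetalSite(
            pdb_id=pdb_id, chain=chain, metal_instance=resnum,
            evidence="both" if len(b["evidence"]) == 2 else next(iter(b["evidence"])),
        )
        positions = []
        for key, res in b["residues"].items():
            if res.resname not in STANDARD_AA3:
                b["nonwater_other"] = True  # hetero neighbour: not a protein residue
                continue
            ref_pos = residue_map.get(res.resnum, res.icode)
            if ref_pos is None:
                site.unmapped.append(res)
                warnings.warn(
                    f"{pdb_id}_{chain} metal {resnum}: residue {res.resname} "
                    f"{res.resnum}{res.icode} not in residue map; excluded",
                    stacklevel=2)
                continue
            if reference is not None and not (1 <= ref_pos <= len(reference.sequence)):
                site.unmapped.append(res)
                continue
            letter = (reference.residue(ref_pos) if reference is not None
                      else STANDARD_AA3[res.resname])
            positions.append((ref_pos, letter))
            site.contact_classes[ref_pos] = b["classes"][key]
        site.coordinating_positions = sorted(set(positions))
        site.water_only = (not site.coordinating_positions and not site.unmapped
                           and not b["nonwater_other"])
        sites.append(site)
    return sites


def template_passes_coverage(template: TemplateStructure,
                             min_coverage: float = 0.70) -> bool:
    """Inclusive coverage test against the mature reference sequence."""
    if template.coverage is None:
        raise InvalidReferenceError(f"{template.pdb_id}: coverage not computed")
    return template.coverage >= min_coverage


def compute_coverage(observed_positions: set, reference) -> float:
    """Fraction of the mature sequence resolved in the structure."""
    mature = reference.mature_positions
    if not mature:
        raise InvalidReferenceError(f"{reference.accession}: mature length 0")
    return len(observed_positions & mature) / len(mature)


def read_ca_coords(pdb_text: str, chain: str) -> dict:
    """CA coordinates of one chain, keyed by (author number, insertion code)."""
    coords = {}
    for line in _coordinate_lines(pdb_text):
        if line[:6] != "ATOM  " or line[21:22].strip() != chain:
            continue
        if line[12:16].strip() != "CA":
            continue
        key = (int(line[22:26]), line[26:27].strip())
        coords.setdefault(key, np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]))
    return coords


def observed_author_numbers(pdb_text: str, chain: str) -> set:
    """(author number, icode) of protein residues resolved in the chain."""
    seen = set()
    for line in _coordinate_lines(pdb_text):
        if line[:6] == "ATOM  " and line[21:22].strip() == chain \
                and line[17:20].strip() in STANDARD_AA3:
            seen.add((int(line[22:26]), line[26:27].strip()))
    return seen


def parse_resolution(pdb_text: str) -> float | None:
    m = re.search(r"^REMARK   2 RESOLUTION\.\s+(\d+\.\d+)", pdb_text, re.M)
    return float(m.group(1)) if m else None


def hetero_codes(pdb_text: str, water_codes=DEFAULT_WATER_CODES) -> set:
    """Distinct non-water HETATM residue codes in MODEL 1."""
    codes = set()
    for line in _coordinate_lines(pdb_text):
        if line[:6] == "HETATM":
            code = line[17:20].strip()
            if code not in water_codes:
                codes.add(code)
    return codes


def binding_mode_label(pdb_text: str, metal_code: str = "MG",
                       water_codes=DEFAULT_WATER_CODES) -> str:
    """Co-crystallisation mode: Mg alone, with other ions, ligands or both."""
    others = hetero_codes(pdb_text, water_codes) - {metal_code}
    has_ions = bool(others & ION_CODES)
    has_ligands = bool(others - ION_CODES)
    if has_ions and has_ligands:
        return "Mg, Ions and Ligands"
    if has_ions:
        return "Mg and Ions"
    if has_ligands:
        return "Mg and Ligands"
    return "Mg"


def build_template(pdb_text: str, pdb_id: str, chain: str, reference,
                   residue_map, metal_code: str = "MG",
                   water_codes=DEFAULT_WATER_CODES,
                   role_label: str = "undetermined") -> TemplateStructure:
    """Parse one chain into a TemplateStructure in reference numbering."""
    contacts = parse_coordination_contacts(pdb_text, metal_code, water_codes)
    site_map = parse_site_records(pdb_text, metal_code)
    sites = build_metal_sites(contacts, site_map, residue_map,
                              pdb_id=pdb_id, water_codes=water_codes,
                              reference=reference)
    observed = set()
    for key in observed_author_numbers(pdb_text, chain):
        ref_pos = residue_map.get(*key)
        if ref_pos is not None:
            observed.add(ref_pos)
    return TemplateStructure(
        pdb_id=pdb_id, chain=chain, accession=reference.accession,
        observed_positions=observed,
        coverage=compute_coverage(observed, reference),
        sites=sites,
        resolution=parse_resolution(pdb_text),
        binding_mode=binding_mode_label(pdb_text, metal_code, water_codes),
        role_label=role_label,
    )


def sites_table(templates) -> "pd.DataFrame":
    """Flat per-position site table (the extract stage's TSV payload)."""
    import pandas as pd

    rows = []
    for tpl in templates:
        for site in tpl.sites:
            if site.water_only:
                rows.append({
                    "pdb_id": tpl.pdb_id, "chain": site.chain,
                    "metal_instance": site.metal_instance, "ref_position": "",
                    "ref_residue": "", "contact_class": "",
                    "evidence": site.evidence, "water_only": True,
                })
                continue
            for pos, letter in site.coordinating_positions:
                rows.append({
                    "pdb_id": tpl.pdb_id, "chain": site.chain,
                    "metal_instance": site.metal_instance, "ref_position": pos,
                    "ref_residue": letter,
                    "contact_class": site.contact_classes.get(pos, "unknown"),
                    "evidence": site.evidence, "water_only": False,
                })
    return pd.DataFrame(rows, columns=[
        "pdb_id", "chain", "metal_instance", "ref_position", "ref_residue",
        "contact_class", "evidence", "water_only"])
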
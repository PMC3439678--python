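"""LINK/SITE/REMARK 800 parsing and metal-site assembly."""

import pytest

from mgsite import pdb_sites
from mgsite.errors import EmptyStructureError, InvalidReferenceError
from mgsite.seqmap import ResidueMap, SequenceRecord

ATOM_STUB = (
    "ATOM      1  CA  ASP A  12       1.000   2.000   3.000  1.00  0.00           C\n"
)


def _pdb(*records) -> str:
    return "".join(r + "\n" for r in records) + ATOM_STUB + "END\n"


LINK_MG_ASP = ("LINK        MG    MG A 301                 OD1 ASP A  12"
               "     1555   1555  2.10")
LINK_MG_HOH = ("LINK        MG    MG A 301                 O   HOH A 401"
               "     1555   1555  2.15")


class TestClassifyContactAtom:
    @pytest.mark.parametrize("resname,atom,expected", [
        ("ASP", "OD1", "sidechain"),
        ("GLY", "O", "backbone"),
        ("HOH", "O", "water"),
        ("THR", "OG1", "sidechain"),
        ("ALA", "OXT", "backbone"),
        ("GTP", "O2G", "other"),
        ("DOD", "O", "water"),
    ])
    def test_classes(self, resname, atom, expected):
        assert pdb_sites.classify_contact_atom(resname, atom) == expected


class TestParseCoordinationContacts:
    def test_two_links_sidechain_and_water(self):
        contacts = pdb_sites.parse_coordination_contacts(_pdb(LINK_MG_ASP, LINK_MG_HOH))
        assert [c.contact_class for c in contacts] == ["sidechain", "water"]
        assert contacts[0].partner.resname == "ASP"
        assert contacts[0].partner_atom == "OD1"
        assert contacts[0].distance == pytest.approx(2.10)
        assert contacts[0].metal_instance == ("A", 301)

    def test_empty_file_is_empty_structure_error(self):
        with pytest.raises(EmptyStructureError):
            pdb_sites.parse_coordination_contacts("")

    def test_metal_on_either_side(self):
        flipped = ("LINK         OD1 ASP A  12                MG    MG A 301"
                   "     1555   1555  2.10")
        contacts = pdb_sites.parse_coordination_contacts(_pdb(flipped))
        assert len(contacts) == 1
        assert contacts[0].partner.resname == "ASP"

    def test_non_metal_links_ignored(self):
        link = ("LINK         SG  CYS A  20                 SG  CYS A  44"
                "     1555   1555  2.05")
        assert pdb_sites.parse_coordination_contacts(_pdb(link)) == []

    def test_malformed_link_collected_and_parse_continues(self):
        bad = "LINK        MG    MG A xyz"
        errors = []
        contacts = pdb_sites.parse_coordination_contacts(
            _pdb(bad, LINK_MG_ASP), errors=errors)
        assert len(contacts) == 1 and len(errors) == 1

    def test_implausible_distance_rejected(self):
        far = ("LINK        MG    MG A 301                 OD1 ASP A  12"
               "     1555   1555 12.00")
        errors = []
        assert pdb_sites.parse_coordination_contacts(_pdb(far), errors=errors) == []
        assert errors

    def test_padding_inside_fixed_fields_is_irrelevant(self):
        # same record with the residue number left- vs right-aligned in its field
        left = LINK_MG_ASP[:22] + "301 " + LINK_MG_ASP[26:]  # resnum left-aligned
        ca = pdb_sites.parse_coordination_contacts(_pdb(left))
        cb = pdb_sites.parse_coordination_contacts(_pdb(LINK_MG_ASP))
        assert ca == cb


SITE_BLOCK = [
    "REMARK 800",
    "REMARK 800 SITE_IDENTIFIER: AC1",
    "REMARK 800 SITE_DESCRIPTION: BINDING SITE FOR RESIDUE MG A 301",
    "SITE     1 AC1  4 ASP A  12  THR A  40  HOH A 401  HOH A 402",
]


class TestParseSiteRecords:
    def test_metal_site_with_four_members(self):
        site_map = pdb_sites.parse_site_records(_pdb(*SITE_BLOCK))
        assert list(site_map) == [("A", 301)]
        residues = site_map[("A", 301)]
        assert len(residues) == 4
        assert residues[0].resname == "ASP" and residues[0].resnum == 12
        assert [r.resname for r in residues[2:]] == ["HOH", "HOH"]

    def test_other_metal_description_gives_empty_map(self):
        block = [
            "REMARK 800 SITE_IDENTIFIER: AC1",
            "REMARK 800 SITE_DESCRIPTION: BINDING SITE FOR RESIDUE ZN A 500",
            "SITE     1 AC1  1 HIS A  10",
        ]
        assert pdb_sites.parse_site_records(_pdb(*block)) == {}

    def test_undescribed_site_warns(self):
        block = ["SITE     1 AC9  1 ASP A  12"]
        with pytest.warns(UserWarning, match="no REMARK 800"):
            assert pdb_sites.parse_site_records(_pdb(*block)) == {}

    def test_continuation_out_of_order_raises(self):
        block = SITE_BLOCK + ["SITE     3 AC1  4 GLU A  50"]
        with pytest.raises(pdb_sites.PdbFormatError):
            pdb_sites.parse_site_records(_pdb(*block))


def _identity_map(n=100):
    return ResidueMap("TOY1", "A", {(i, ""): i for i in range(1, n + 1)})


class TestBuildMetalSites:
    def test_water_dropped_but_site_kept(self):
        contacts = pdb_sites.parse_coordination_contacts(_pdb(LINK_MG_ASP, LINK_MG_HOH))
        sites = pdb_sites.build_metal_sites(contacts, {}, _identity_map(), pdb_id="TOY1")
        assert len(sites) == 1
        (site,) = sites
        assert site.coordinating_positions == [(12, "D")]
        assert not site.water_only
        assert site.evidence == "LINK"

    def test_all_water_site_flagged(self):
        links = [
            ("LINK        MG    MG A 302                 O   HOH A 401"
             "     1555   1555  2.15"),
            ("LINK        MG    MG A 302                 O   HOH A 402"
             "     1555   1555  2.20"),
        ]
        contacts = pdb_sites.parse_coordination_contacts(_pdb(*links))
        (site,) = pdb_sites.build_metal_sites(contacts, {}, _identity_map())
        assert site.water_only and site.coordinating_positions == []

    def test_link_and_site_evidence_union(self):
        contacts = pdb_sites.parse_coordination_contacts(_pdb(*SITE_BLOCK, LINK_MG_ASP))
        site_map = pdb_sites.parse_site_records(_pdb(*SITE_BLOCK, LINK_MG_ASP))
        (site,) = pdb_sites.build_metal_sites(contacts, site_map, _identity_map())
        assert site.evidence == "both"
        assert [p for p, _ in site.coordinating_positions] == [12, 40]
        # LINK atom detail classifies position 12; SITE alone cannot
        assert site.contact_classes[12] == "sidechain"
        assert site.contact_classes[40] == "unknown"

    def test_unmapped_residue_excluded_with_warning(self):
        contacts = pdb_sites.parse_coordination_contacts(_pdb(LINK_MG_ASP))
        empty = ResidueMap("TOY1", "A", {})
        with pytest.warns(UserWarning, match="not in residue map"):
            (site,) = pdb_sites.build_metal_sites(contacts, {}, empty)
        assert site.coordinating_positions == []
        assert not site.water_only  # an unmapped protein residue is not water


class TestTemplateCoverage:
    def _template(self, coverage):
        return pdb_sites.TemplateStructure(
            pdb_id="TOY1", chain="A", accession="P1",
            observed_positions=set(), coverage=coverage, sites=[])

    def test_boundary_inclusive(self):
        assert pdb_sites.template_passes_coverage(self._template(0.70), 0.70)

    def test_just_below_boundary(self):
        assert not pdb_sites.template_passes_coverage(self._template(0.69), 0.70)

    def test_signal_peptide_shrinks_denominator(self):
        ref = SequenceRecord("P1", "A" * 110, signal_peptide=(1, 10))
        observed = set(range(21, 101))  # 80 mature positions
        assert pdb_sites.compute_coverage(observed, ref) == pytest.approx(0.80)

    def test_mature_length_zero_is_error(self):
        ref = SequenceRecord("P1", "A" * 10, signal_peptide=(1, 10))
        with pytest.raises(InvalidReferenceError):
            pdb_sites.compute_coverage({1, 2}, ref)


def test_binding_mode_labels():
    mg_only = _pdb("HETATM   90 MG    MG A 301       0.000   0.000   0.000"
                   "  1.00  0.00          MG")
    assert pdb_sites.binding_mode_label(mg_only) == "Mg"
    with_ion = _pdb(
        "HETATM   90 MG    MG A 301       0.000   0.000   0.000  1.00  0.00          MG",
        "HETATM   91 ZN    ZN A 302       9.000   0.000   0.000  1.00  0.00          ZN")
    assert pdb_sites.binding_mode_label(with_ion) == "Mg and Ions"
    with_both = _pdb(
        "HETATM   90 MG    MG A 301       0.000   0.000   0.000  1.00  0.00          MG",
        "HETATM   91 ZN    ZN A 302       9.000   0.000   0.000  1.00  0.00          ZN",
        "HETATM   92  C1  GTP A 303       5.000   0.000   0.000  1.00  0.00           C")
    assert pdb_sites.binding_mode_label(with_both) == "Mg, Ions and Ligands"


def test_model_one_only_and_altloc_filter():
    text = (
        "MODEL        1\n"
        "ATOM      1  CA  ASP A  12       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CA BASP A  13       1.000   2.000   3.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      3  CA  ASP A  14       9.000   9.000   9.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "END\n")
    observed = pdb_sites.observed_author_numbers(text, "A")
    assert observed == {(12, "")}  # model 2 and altloc B excluded
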
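"""Sequences and PDB-author-numbering to reference-position maps.

Reference coordinates are 1-based and inclusive everywhere; PDB author
numbers are opaque keys (they may be negative and may carry insertion
codes).  Curated mapping files (SIFTS-like TSV) are the primary source; a
simple identity-scored global alignment is the fallback for fixtures and
edge cases.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from . import align
from .errors import MappingError

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

MAP_COLUMNS = ["pdb_id", "chain", "author_number", "ins_code", "ref_position"]


@dataclass(frozen=True)
class SequenceRecord:
    """One reference protein sequence with its annotation flags."""

    accession: str
    sequence: str
    organism: str = ""
    is_fragment: bool = False
    signal_peptide: tuple[int, int] | None = None  # inclusive, 1-based

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: non-amino-acid letters {sorted(bad)}")
        if self.signal_peptide is not None:
            lo, hi = self.signal_peptide
            if lo != 1 or hi < lo or hi > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: signal peptide {self.signal_peptide} must "
                    "start at position 1 and lie within the sequence"
                )

    @property
    def mature_positions(self) -> set[int]:
        """Reference positions outside the signal peptide."""
        start = 1 if self.signal_peptide is None else self.signal_peptide[1] + 1
        return set(range(start, len(self.sequence) + 1))

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]


@dataclass
class ResidueMap:
    """PDB author numbering -> reference position for one chain."""

    pdb_id: str
    chain: str
    entries: dict = field(default_factory=dict)  # (author_number, ins_code) -> ref pos
    substituted: set = field(default_factory=set)  # ref positions mapped across a mismatch

    def __post_init__(self):
        refs = list(self.entries.values())
        if len(set(refs)) != len(refs):
            seen, dup = {}, []
            for key, ref in self.entries.items():
                if ref in seen:
                    dup.append((seen[ref], key, ref))
                seen[ref] = key
            raise MappingError(f"{self.pdb_id}_{self.chain}: non-injective map: {dup}")
        if any(r < 1 for r in refs):
            raise MappingError(f"{self.pdb_id}_{self.chain}: reference positions must be >= 1")

    def get(self, author_number: int, ins_code: str = "") -> int | None:
        return self.entries.get((author_number, ins_code))

    def __len__(self) -> int:
        return len(self.entries)


def read_fasta(source) -> list[SequenceRecord]:
    """Read records whose description carries key=value tags.

    Recognised tags: ``organism``, ``fragment`` (yes/no), ``signal_peptide``
    (``start-end``).  The first word of the header is the accession.
    """
    handle = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        tags = dict(t.split("=", 1) for t in rec.description.split()[1:] if "=" in t)
        sp = None
        if "signal_peptide" in tags:
            lo, hi = tags["signal_peptide"].split("-")
            sp = (int(lo), int(hi))
        records.append(
            SequenceRecord(
                accession=rec.id,
                sequence=str(rec.seq).upper(),
                organism=tags.get("organism", ""),
                is_fragment=tags.get("fragment", "no").lower() in {"yes", "true", "1"},
                signal_peptide=sp,
            )
        )
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tags = []
            if rec.organism:
                tags.append(f"organism={rec.organism}")
            if rec.is_fragment:
                tags.append("fragment=yes")
            if rec.signal_peptide:
                tags.append(f"signal_peptide={rec.signal_peptide[0]}-{rec.signal_peptide[1]}")
            header = " ".join([rec.accession] + tags)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def load_residue_maps(tsv_text: str) -> dict[tuple[str, str], ResidueMap]:
    """Parse a mapping TSV into one ResidueMap per (pdb_id, chain).

    Columns: pdb_id, chain, author_number, ins_code, ref_position (header
    optional).  Duplicate author keys and non-injective maps are rejected.
    """
    text = tsv_text.strip()
    if not text:
        return {}
    first = text.splitlines()[0].lower().split("\t")
    header = 0 if first[:2] == ["pdb_id", "chain"] else None
    df = pd.read_csv(
        io.StringIO(text), sep="\t", header=header,
        names=MAP_COLUMNS if header is None else None,
        dtype={"pdb_id": str, "chain": str, "ins_code": str},
        keep_default_na=False,
    )
    df.columns = MAP_COLUMNS
    maps: dict[tuple[str, str], ResidueMap] = {}
    for (pdb_id, chain), grp in df.groupby(["pdb_id", "chain"], sort=True):
        entries: dict = {}
        for row in grp.itertuples(index=False):
            key = (int(row.author_number), str(row.ins_code).strip())
            if key in entries:
                raise MappingError(
                    f"{pdb_id}_{chain}: duplicate author number {key} "
                    f"(maps to {entries[key]} and {row.ref_position})"
                )
            entries[key] = int(row.ref_position)
        maps[(str(pdb_id), str(chain))] = ResidueMap(str(pdb_id), str(chain), entries)
    return maps


def load_residue_map(tsv_text: str) -> ResidueMap:
    """As :func:`load_residue_maps` but for a single-chain file."""
    maps = load_residue_maps(tsv_text)
    if not maps:
        return ResidueMap("", "", {})
    if len(maps) > 1:
        raise MappingError(f"expected one chain, found {sorted(maps)}")
    return next(iter(maps.values()))


def align_map(seqres_sequence: str, reference_sequence: str,
              pdb_id: str = "", chain: str = "") -> ResidueMap:
    """Map SEQRES index (used as author number) to reference position.

    Global alignment with identity scoring (match +1, mismatch 0, gap -1);
    only non-gap/non-gap columns are mapped, and mismatched columns are
    recorded in ``substituted``.
    """
    aln = align.global_align(
        seqres_sequence, reference_sequence,
        score_fn=align.identity_score, gap_open=0, gap_extend=1,
    )
    entries, substituted = {}, set()
    for i, j in aln.pairs:
        if i is None or j is None:
            continue
        entries[(i + 1, "")] = j + 1
        if seqres_sequence[i] != reference_sequence[j]:
            substituted.add(j + 1)
    return ResidueMap(pdb_id, chain, entries, substituted)


def union_sites_per_accession(templates) -> dict[str, dict[int, list[str]]]:
    """Union of coordinating positions over all structures of one accession.

    Water-only sites never contribute.  The returned inner mapping carries,
    per reference position, the sorted list of contributing PDB ids
    (provenance).  Idempotent and order-independent.
    """
    merged: dict[str, dict[int, set]] = {}
    for tpl in templates:
        acc = tpl.accession
        bucket = merged.setdefault(acc, {})
        for site in tpl.sites:
            if site.water_only:
                continue
            for pos, _res in site.coordinating_positions:
                bucket.setdefault(pos, set()).add(tpl.pdb_id)
    return {
        acc: {pos: sorted(pdbs) for pos, pdbs in sorted(bucket.items())}
        for acc, bucket in merged.items()
    }
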
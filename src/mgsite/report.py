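"""Human-readable and TSV reports of the annotation results.

The per-target block mirrors the coloured residue view of the annotation
web resource: one line per predicted binding position with its template
residue, target residue and substitution class (green = identical,
yellow = similar, white = different), the contributing template structures
and a star marking clusters whose templates have a documented structural
or functional magnesium role.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CLASS_COLOR = {"identical": "green", "similar": "yellow", "different": "white"}
ROLE_MARK = {"functional": "* (EC)", "structural": "*", "undetermined": ""}


def target_block(sites) -> str:
    """Text block for one target's transferred sites."""
    sites = [s for s in sites if s.substitution_class != "untransferred"]
    if not sites:
        return ""
    acc = sites[0].target_accession
    lines = [f"Target: {acc}"]
    role = sites[0].role_label
    mark = ROLE_MARK.get(role, "")
    lines.append(f"Cluster: {sites[0].cluster_id}"
                 + (f"  {mark}" if mark else ""))
    pdbs = sorted({p for s in sites for p in s.pdb_ids})
    lines.append(f"Templates: {', '.join(pdbs)}")
    lines.append("pos\ttemplate\ttarget\tclass\tcolor")
    for s in sorted(sites, key=lambda s: s.target_position):
        lines.append(f"{s.target_residue} {s.target_position}\t"
                     f"{s.template_residue}\t{s.target_residue}\t"
                     f"{s.substitution_class}\t"
                     f"{CLASS_COLOR[s.substitution_class]}")
    return "\n".join(lines) + "\n"


def write_reports(result, out_dir, frequency_table: pd.DataFrame | None = None,
                  rmsd_rows: list | None = None) -> None:
    """Write the annotation table, per-target blocks and summary TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.annotation_table.to_csv(out / "annotation.tsv", sep="\t", index=False)

    by_target: dict[str, list] = {}
    for s in result.transferred:
        by_target.setdefault(s.target_accession, []).append(s)
    with open(out / "targets.txt", "w") as fh:
        for acc in sorted(by_target):
            block = target_block(by_target[acc])
            if block:
                fh.write(block + "\n")

    if frequency_table is not None:
        frequency_table.to_csv(out / "residue_frequencies.tsv", sep="\t", index=False)
    if rmsd_rows:
        pd.DataFrame(rmsd_rows, columns=["cluster_id", "pdb_a", "pdb_b", "rmsd"]) \
            .to_csv(out / "cluster_rmsd.tsv", sep="\t", index=False)
    if result.enrichments:
        pd.DataFrame([vars(e) for e in result.enrichments]) \
            .to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
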
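"""End-to-end orchestration: extract -> cluster -> HMM -> transfer -> validate."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import clustering, profile_hmm, transfer
from .config import Thresholds, DEFAULT_THRESHOLDS
from .pdb_sites import template_passes_coverage


@dataclass
class PipelineResult:
    clusters: list
    singletons: list
    edges: list
    transferred: list
    enrichments: list = field(default_factory=list)

    @property
    def annotation_table(self) -> pd.DataFrame:
        return transfer.transfer_table(self.transferred)


def build_cluster_models(clusters, records_by_accession,
                         pseudocount: float = 1.0) -> None:
    """Build the star MSA and profile HMM of every annotating cluster.

    The anchor is the longest template sequence of the cluster; other
    templates are aligned as members.
    """
    for cluster in clusters:
        if not cluster.is_annotating:
            continue
        template_records = [records_by_accession[a] for a in cluster.templates]
        anchor = max(template_records, key=lambda r: (len(r.sequence), r.accession))
        members = [records_by_accession[a] for a in cluster.members]
        cluster.msa = profile_hmm.build_cluster_msa(members, anchor)
        cluster.hmm = profile_hmm.build_profile_hmm(cluster.msa,
                                                    pseudocount=pseudocount)


def run_pipeline(records, templates,
                 thresholds: Thresholds = DEFAULT_THRESHOLDS,
                 term_table: pd.DataFrame | None = None) -> PipelineResult:
    """Run the whole annotation-transfer pipeline on in-memory inputs.

    ``templates`` are TemplateStructure objects already mapped to reference
    numbering; those failing the mature-sequence coverage bound are
    dropped here.  When ``term_table`` (accession, term) is given, term
    enrichment is computed and validated terms attached to the clusters.
    """
    accepted = [t for t in templates
                if template_passes_coverage(t, thresholds.template_min_coverage)]
    clusters, singletons, edges = clustering.cluster_records(
        records, accepted, thresholds)
    records_by_acc = {r.accession: r for r in records}
    build_cluster_models(clusters, records_by_acc)
    transferred = []
    for cluster in clusters:
        if cluster.is_annotating:
            transferred.extend(
                transfer.transfer_cluster(cluster, records_by_acc, thresholds))
    enrichments = []
    if term_table is not None and len(term_table):
        enrichments = transfer.enrich_clusters(
            clusters, term_table, alpha=thresholds.enrichment_alpha)
    return PipelineResult(clusters=clusters, singletons=singletons, edges=edges,
                          transferred=transferred, enrichments=enrichments)
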
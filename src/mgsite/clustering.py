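"""Sequence-similarity graph and annotation clusters.

Two sequences are connected when a local BLOSUM62 alignment gives >=40%
identity over >=90% coverage of the longer sequence (both inclusive, both
configurable).  Annotation clusters are the connected components of that
graph; size-1 components are singletons and receive no cluster-based
annotation.  A cluster holding at least one accepted metal-binding
structural template is an *annotating* cluster: every other member is a
transfer target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from . import align
from .config import Thresholds, DEFAULT_THRESHOLDS


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity-graph edge (stored with a < b)."""

    accession_a: str
    accession_b: str
    identity: float  # percent
    coverage: float  # percent

    def __post_init__(self):
        if self.accession_a >= self.accession_b:
            raise ValueError("edge endpoints must satisfy a < b")
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity/coverage must be percentages")


@dataclass
class Cluster:
    """A connected component of the similarity graph."""

    cluster_id: str
    members: list  # sorted accessions
    templates: list = field(default_factory=list)  # template accessions
    template_structures: list = field(default_factory=list)
    hmm: object = None
    msa: object = None
    validated_terms: list = field(default_factory=list)

    @property
    def is_annotating(self) -> bool:
        return any(t.transferable_sites for t in self.template_structures)

    @property
    def targets(self) -> list:
        return [m for m in self.members if m not in set(self.templates)]


def pairwise_identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and coverage (percent) from a local BLOSUM62 alignment.

    Identity is identical pairs over aligned columns (gaps included in the
    denominator, as in BLAST); coverage is the fraction of the *longer*
    sequence inside the aligned region, so a short fragment cannot claim
    high overlap against a full-length chain.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compare empty sequences")
    # canonical argument order keeps the traceback orientation fixed
    swap = len(seq_b) > len(seq_a) or (len(seq_b) == len(seq_a) and seq_b < seq_a)
    longer, shorter = (seq_b, seq_a) if swap else (seq_a, seq_b)
    aln = align.local_align(longer, shorter)
    if not aln.pairs:
        return 0.0, 0.0
    columns = len(aln.pairs)
    identical = sum(
        1 for i, j in aln.pairs
        if i is not None and j is not None and longer[i] == shorter[j]
    )
    longer_residues = sum(1 for i, _ in aln.pairs if i is not None)
    return 100.0 * identical / columns, 100.0 * longer_residues / len(longer)


def build_graph(records, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[SimilarityEdge]:
    """All-vs-all similarity edges passing the identity/coverage thresholds."""
    by_acc = sorted(records, key=lambda r: r.accession)
    edges = []
    for i, ra in enumerate(by_acc):
        for rb in by_acc[i + 1:]:
            ident, cov = pairwise_identity_coverage(ra.sequence, rb.sequence)
            if ident >= thresholds.min_identity and cov >= thresholds.min_coverage:
                edges.append(SimilarityEdge(ra.accession, rb.accession,
                                            round(ident, 2), round(cov, 2)))
    return edges


def connected_components(nodes, edges) -> tuple[list[Cluster], list[str]]:
    """Split the thresholded graph into clusters and singletons.

    Cluster ids are assigned deterministically by sorting components on
    their smallest member accession.
    """
    node_set = set(nodes)
    graph = nx.Graph()
    graph.add_nodes_from(node_set)
    for e in edges:
        if e.accession_a not in node_set or e.accession_b not in node_set:
            raise ValueError(f"edge references unknown node: {e}")
        graph.add_edge(e.accession_a, e.accession_b)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    clusters, singletons = [], []
    for comp in comps:
        if len(comp) == 1:
            singletons.append(comp[0])
        else:
            clusters.append(Cluster(cluster_id=f"C{len(clusters) + 1:04d}", members=comp))
    return clusters, sorted(singletons)


def attach_templates(clusters, singletons, templates) -> list[Cluster]:
    """Attach accepted structural templates to their clusters.

    A template whose accession sits in a cluster flags that cluster as
    annotating; a template that is itself a singleton annotates nothing.
    Returns the annotating clusters.
    """
    by_member = {m: c for c in clusters for m in c.members}
    singleton_set = set(singletons)
    for tpl in sorted(templates, key=lambda t: (t.accession, t.pdb_id)):
        cluster = by_member.get(tpl.accession)
        if cluster is None:
            if tpl.accession not in singleton_set:
                warnings.warn(
                    f"template {tpl.pdb_id} ({tpl.accession}) matches no graph "
                    "node; treated as a singleton", stacklevel=2)
            else:
                warnings.warn(
                    f"template {tpl.pdb_id} ({tpl.accession}) is a singleton; "
                    "no targets annotated from it", stacklevel=2)
            continue
        if tpl.accession not in cluster.templates:
            cluster.templates.append(tpl.accession)
        cluster.template_structures.append(tpl)
    return [c for c in clusters if c.is_annotating]


def cluster_records(records, templates=(),
                    thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Convenience: graph -> components -> template attachment.

    Fragment-flagged records are excluded before clustering.  Returns
    (clusters, singletons, edges).
    """
    usable = [r for r in records if not r.is_fragment]
    edges = build_graph(usable, thresholds)
    clusters, singletons = connected_components(
        [r.accession for r in usable], edges)
    attach_templates(clusters, singletons, templates)
    return clusters, singletons, edges
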
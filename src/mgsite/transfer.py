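"""Transfer of metal-binding positions and validated terms to cluster members.

Binding positions travel from a cluster's structural templates to each
member through the cluster profile HMM: a template site position owns a
match state, the member's Viterbi path says which member residue (if any)
sits in that state, and the substitution is classed with BLOSUM62 —
identical, similar (positive score) or different.  Term inheritance
(ontology/domain annotations) is validated per cluster with a
hypergeometric upper-tail test, Bonferroni-corrected, and inherited only
below the significance threshold (default p < 0.01); an optional
permutation bootstrap estimates an empirical threshold from the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import blosum, profile_hmm
from .config import Thresholds, DEFAULT_THRESHOLDS
from .errors import MembershipError


@dataclass(frozen=True)
class TransferredSite:
    """One binding position predicted on a target sequence."""

    target_accession: str
    target_position: int | None  # None when deleted in the target
    template_residue: str
    target_residue: str | None
    substitution_class: str  # identical | similar | different | untransferred
    template_accession: str
    pdb_ids: tuple
    cluster_id: str
    metal_count: int = 1
    role_label: str = "undetermined"  # functional | structural | undetermined
    reason: str = ""  # non-empty for untransferred positions


@dataclass(frozen=True)
class TermEnrichment:
    """Hypergeometric enrichment of one term in one cluster."""

    cluster_id: str
    term: str
    k: int  # members carrying the term
    n: int  # cluster size
    K: int  # background sequences carrying the term
    N: int  # background size
    p_raw: float
    p_corrected: float
    validated: bool


def classify_substitution(template_res: str, target_res: str,
                          matrix=None, cutoff: int = 0) -> str:
    """identical / similar / different, target read relative to template.

    "Similar" means a BLOSUM62 score strictly above ``cutoff`` (default 0)
    between two non-identical residues; X never counts as similar.
    """
    if template_res == target_res:
        return "identical"
    if "X" in (template_res, target_res):
        return "different"
    s = blosum.score(template_res, target_res) if matrix is None \
        else matrix[(template_res, target_res)]
    return "similar" if s > cutoff else "different"


def transfer_sites(cluster, target_accession: str, records_by_accession: dict,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[TransferredSite]:
    """Map every template binding position onto one target sequence.

    Positions from multiple templates are merged by target position (union
    semantics, provenance concatenated).  Water-only sites never
    contribute; positions deleted in the target or unresolvable through
    the MSA are reported as untransferred with a reason.
    """
    if cluster.hmm is None:
        raise ValueError(f"{cluster.cluster_id}: cluster HMM not built")
    if target_accession not in set(cluster.members):
        raise MembershipError(f"{target_accession} is not in {cluster.cluster_id}")
    target = records_by_accession[target_accession]
    path = profile_hmm.viterbi_align(cluster.hmm, target.sequence,
                                     accession=target_accession)

    msa = cluster.msa
    col_to_match = {c: k + 1 for k, c in enumerate(msa.match_columns)}

    merged: dict = {}
    untransferred: list[TransferredSite] = []
    for tpl in sorted(cluster.template_structures, key=lambda t: (t.accession, t.pdb_id)):
        tpl_row = msa.accession_row(tpl.accession)
        pos_to_col = msa.position_to_column(tpl_row)
        n_metals = len(tpl.transferable_sites)
        for site in tpl.transferable_sites:
            for pos, letter in site.coordinating_positions:
                common = dict(
                    target_accession=target_accession,
                    template_residue=letter,
                    template_accession=tpl.accession,
                    cluster_id=cluster.cluster_id,
                    metal_count=n_metals,
                    role_label=tpl.role_label,
                )
                col = pos_to_col.get(pos)
                k = col_to_match.get(col) if col is not None else None
                if k is None:
                    untransferred.append(TransferredSite(
                        target_position=None, target_residue=None,
                        substitution_class="untransferred",
                        pdb_ids=(tpl.pdb_id,),
                        reason="template residue not on a match column", **common))
                    continue
                tpos = path.target_position_of_match(k)
                if tpos is None:
                    untransferred.append(TransferredSite(
                        target_position=None, target_residue=None,
                        substitution_class="untransferred",
                        pdb_ids=(tpl.pdb_id,),
                        reason="deleted in target", **common))
                    continue
                tres = target.residue(tpos)
                key = tpos
                if key in merged:
                    prev = merged[key]
                    merged[key] = replace(
                        prev, pdb_ids=tuple(sorted(set(prev.pdb_ids) | {tpl.pdb_id})))
                else:
                    merged[key] = TransferredSite(
                        target_position=tpos, target_residue=tres,
                        substitution_class=classify_substitution(
                            letter, tres, cutoff=thresholds.similar_cutoff),
                        pdb_ids=(tpl.pdb_id,), **common)
    return [merged[k] for k in sorted(merged)] + untransferred


def transfer_cluster(cluster, records_by_accession: dict,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[TransferredSite]:
    """Transfer sites to every non-template member of an annotating cluster."""
    out = []
    for acc in cluster.targets:
        out.extend(transfer_sites(cluster, acc, records_by_accession, thresholds))
    return out


def term_enrichment(cluster_id: str, term: str, k: int, n: int, K: int, N: int,
                    n_terms_tested: int, alpha: float = 0.01) -> TermEnrichment:
    """Hypergeometric upper tail P(X >= k) with Bonferroni correction.

    X counts term carriers in a size-n draw from a background of N
    sequences of which K carry the term.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"impossible counts k={k} n={n} K={K} N={N}")
    p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    p_corr = min(1.0, p_raw * n_terms_tested)
    return TermEnrichment(cluster_id=cluster_id, term=term, k=k, n=n, K=K, N=N,
                          p_raw=p_raw, p_corrected=p_corr,
                          validated=p_corr < alpha)


def enrich_clusters(clusters, term_table: pd.DataFrame,
                    alpha: float = 0.01,
                    bonferroni: str = "cluster") -> list[TermEnrichment]:
    """Enrichment of every term in every cluster.

    ``term_table`` has columns (accession, term); the background is the
    whole table's accession universe.  The Bonferroni multiplier is the
    number of distinct terms tested within the cluster (``cluster``) or
    over the whole table (``global``).
    """
    universe = set(term_table["accession"])
    for c in clusters:
        universe |= set(c.members)
    N = len(universe)
    carriers = term_table.groupby("term")["accession"].apply(set)
    n_global = len(carriers)
    results = []
    for cluster in clusters:
        members = set(cluster.members)
        n = len(members)
        cluster_terms = sorted(t for t, accs in carriers.items() if accs & members)
        multiplier = len(cluster_terms) if bonferroni == "cluster" else n_global
        for term in cluster_terms:
            accs = carriers[term]
            results.append(term_enrichment(
                cluster.cluster_id, term,
                k=len(accs & members), n=n, K=len(accs), N=N,
                n_terms_tested=max(multiplier, 1), alpha=alpha))
        cluster.validated_terms = [r.term for r in results
                                   if r.cluster_id == cluster.cluster_id and r.validated]
    return results


def bootstrap_alpha(clusters, term_table: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0, bonferroni: str = "cluster") -> float:
    """Permutation null for the per-cluster minimum corrected p-value.

    Term assignments are shuffled over the sequence universe (term
    multiset preserved); each replicate records its per-cluster minimum
    Bonferroni-corrected p, and the 1st percentile of that null
    distribution is returned as an empirical significance threshold.  The
    decision rule of the pipeline stays the fixed alpha unless the caller
    adopts the returned value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if term_table["term"].nunique() <= 1:
        warnings.warn("degenerate term table (single term); returning 0.01",
                      stacklevel=2)
        return 0.01
    rng = np.random.default_rng(seed)
    accessions = sorted(set(term_table["accession"])
                        | {m for c in clusters for m in c.members})
    minima = []
    for _ in range(n_boot):
        perm = dict(zip(accessions, rng.permutation(accessions)))
        shuffled = term_table.assign(
            accession=term_table["accession"].map(perm))
        results = enrich_clusters(clusters, shuffled, alpha=1.1,
                                  bonferroni=bonferroni)
        per_cluster: dict = {}
        for r in results:
            per_cluster[r.cluster_id] = min(
                per_cluster.get(r.cluster_id, 1.0), r.p_corrected)
        minima.extend(per_cluster.values() if per_cluster else [1.0])
    return float(np.percentile(minima, 1))


def transfer_table(sites) -> pd.DataFrame:
    """Flat annotation table (one row per transferred position)."""
    rows = []
    for s in sites:
        rows.append({
            "target_accession": s.target_accession,
            "position": s.target_position if s.target_position is not None else "",
            "template_res": s.template_residue,
            "target_res": s.target_residue or "",
            "class": s.substitution_class,
            "template_pdb": ";".join(s.pdb_ids),
            "cluster_id": s.cluster_id,
            "role_label": s.role_label,
            "metal_count": s.metal_count,
            "reason": s.reason,
        })
    return pd.DataFrame(rows, columns=[
        "target_accession", "position", "template_res", "target_res", "class",
        "template_pdb", "cluster_id", "role_label", "metal_count", "reason"])
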
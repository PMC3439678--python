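"""Structural and statistical summaries: Kabsch RMSD, residue frequencies,
ontology depth.

The Kabsch algorithm gives the closed-form least-squares rigid
superposition of two paired point sets (SVD of the cross-covariance, with
the determinant-sign correction that excludes reflections).  Cluster
structural homogeneity is summarised as the mean +/- population SD of the
pairwise CA RMSD over template pairs, pairing atoms through shared HMM
match columns.  Binding-residue frequency tables drive the
backbone/side-chain composition summaries, and ontology term depth (longest
path from the root) selects the most specific annotation per sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import OntologyError


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid superposition of B onto A."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float  # angstrom


def kabsch_rmsd(coords_a, coords_b) -> Superposition:
    """Least-squares rigid superposition (Kabsch) of two paired point sets.

    Returns rotation R and translation t minimising ||A - (B R + t)||, and
    the RMSD after superposition.  Requires N >= 3 non-collinear points.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"paired Nx3 coordinate sets required, got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    B_fit = B0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((A0 - B_fit) ** 2, axis=1))))
    t = ca - cb @ R.T
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def cluster_rmsd_summary(templates, msa, ca_coords: dict,
                         residue_maps: dict) -> tuple[float, float, list]:
    """Mean +/- population SD of pairwise CA RMSD over cluster templates.

    Atom pairing goes through the cluster MSA: a match column contributes
    when both templates resolve a CA there.  ``ca_coords[pdb_id]`` maps
    (author number, icode) to coordinates; ``residue_maps[pdb_id]`` is the
    chain's ResidueMap.  Pairs with fewer than 3 shared CA atoms are
    skipped with a warning.  Returns (mean, sd, pairwise list).
    """
    if len(templates) < 2:
        raise ValueError("need at least two templates")
    match_cols = set(msa.match_columns)

    def ref_to_xyz(tpl):
        inverse = {}
        rmap = residue_maps[tpl.pdb_id]
        coords = ca_coords[tpl.pdb_id]
        for key, ref in rmap.entries.items():
            if key in coords:
                inverse[ref] = coords[key]
        row = msa.accession_row(tpl.accession)
        pos_to_col = msa.position_to_column(row)
        return {pos_to_col[p]: xyz for p, xyz in inverse.items()
                if p in pos_to_col and pos_to_col[p] in match_cols}

    by_col = [ref_to_xyz(t) for t in templates]
    pairwise = []
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            shared = sorted(set(by_col[i]) & set(by_col[j]))
            if len(shared) < 3:
                warnings.warn(
                    f"{templates[i].pdb_id} vs {templates[j].pdb_id}: fewer than "
                    "3 shared CA pairs; skipped", stacklevel=2)
                continue
            A = np.array([by_col[i][c] for c in shared])
            B = np.array([by_col[j][c] for c in shared])
            pairwise.append((templates[i].pdb_id, templates[j].pdb_id,
                             kabsch_rmsd(A, B).rmsd))
    if not pairwise:
        raise ValueError("no template pair shares enough CA atoms")
    values = np.array([r for _, _, r in pairwise])
    return float(values.mean()), float(values.std()), pairwise


def residue_binding_frequencies(sites=None, transferred=None) -> pd.DataFrame:
    """Amino-acid frequency table of metal-coordinating positions.

    Template structures contribute one count per site-residue incidence,
    split by contact class (backbone vs side chain; positions without
    atom-level evidence are excluded from the split).  Transferred target
    annotations are counted by residue type only.  Frequencies normalise
    to 1 within each split.
    """
    rows = []
    for site in sites or []:
        if site.water_only:
            continue
        for pos, letter in site.coordinating_positions:
            cls = site.contact_classes.get(pos, "unknown")
            if cls in ("backbone", "sidechain"):
                rows.append({"split": f"template_{cls}", "residue": letter})
    for ts in transferred or []:
        if ts.target_residue:
            rows.append({"split": "target", "residue": ts.target_residue})
    if not rows:
        raise ValueError("no countable binding positions")
    df = pd.DataFrame(rows)
    out = (df.groupby(["split", "residue"]).size().rename("count").reset_index())
    out["frequency"] = out.groupby("split")["count"].transform(lambda s: s / s.sum())
    return out.sort_values(["split", "residue"]).reset_index(drop=True)


def deepest_terms(annotated_terms, parent_edges, root: str | None = None) -> set:
    """Terms most distant from the ontology root (longest-path depth).

    ``parent_edges`` is an iterable of (child, parent).  Depth is the
    longest path from the root along child edges; among the annotated
    terms, all terms of maximal depth are returned.  Terms absent from the
    ontology are skipped with a warning; a cyclic edge list is an error.
    """
    g = nx.DiGraph()
    for child, parent in parent_edges:
        g.add_edge(parent, child)  # root-to-leaf direction
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError("ontology parent edges contain a cycle")
    if root is None:
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(f"expected a single root, found {sorted(roots)}")
        root = roots[0]
    depth = {root: 0}
    for node in nx.topological_sort(g):
        if node not in depth:
            continue  # unreachable from the root
        for child in g.successors(node):
            depth[child] = max(depth.get(child, 0), depth[node] + 1)

    usable = {}
    for term in set(annotated_terms):
        if term not in depth:
            warnings.warn(f"term {term!r} not in ontology; skipped", stacklevel=2)
            continue
        usable[term] = depth[term]
    if not usable:
        return set()
    dmax = max(usable.values())
    return {t for t, d in usable.items() if d == dmax}
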
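"""Self-contained validation studies run on synthetic inputs.

These routines regenerate their inputs from a seed, run the pipeline, and
measure how well it does against the generator's ground truth: the
multi-site parsing topology (several ions per structure, one of them
water-coordinated only), exact recovery of the generating families by the
similarity graph, positional recovery of planted binding sites through the
cluster HMM, type-I control of the term-inheritance test, and rigid-motion
invariance of the superposition code.  Both the test suite and the
reproduction script drive the pipeline through them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fixtures, metrics, pdb_sites, pipeline, seqmap, transfer
from .clustering import Cluster


def multisite_parse_summary(seed: int = 0) -> dict:
    """Parse a synthetic three-ion structure and summarise its sites.

    The fixture mirrors the archetypal multi-site case: one chain with
    three magnesium ions, of which one is coordinated only by waters and
    the other two by four and by two protein residues.
    """
    rng = np.random.default_rng(seed)
    seq = fixtures.draw_root(90, (10, 22, 35, 48, 60, 75), rng)
    pdb_text, mapping = fixtures.write_toy_pdb(
        seq, [10, 22, 35, 48, 60, 75], n_metals=2,
        site_groups=[[10, 22, 35, 48], [60, 75]],
        include_water_only_site=True, seed=seed)
    rec = seqmap.SequenceRecord("SYNT", seq)
    tpl = pdb_sites.build_template(pdb_text, "SYN1", "A", rec,
                                   seqmap.load_residue_map(mapping))
    protein_sites = sorted((len(s.coordinating_positions)
                            for s in tpl.transferable_sites), reverse=True)
    return {
        "n_metal_sites": len(tpl.sites),
        "n_water_only": sum(s.water_only for s in tpl.sites),
        "protein_site_sizes": protein_sites,
        "coverage": tpl.coverage,
    }


def three_family_partition_fraction(seed: int = 0,
                                    substitution_rate: float = 0.05) -> float:
    """Fraction of generating families recovered exactly as clusters."""
    records, _, assignment = fixtures.three_family_records(
        seed=seed, substitution_rate=substitution_rate)
    result = pipeline.run_pipeline(records, [])
    got = {frozenset(c.members) for c in result.clusters} | \
          {frozenset({s}) for s in result.singletons}
    families = {fam: frozenset(a for a, f in assignment.items() if f == fam)
                for fam in "ABC"}
    return sum(members in got for members in families.values()) / len(families)


def family_recovery_rate(n_seeds: int = 100, substitution_rate: float = 0.15,
                         indel_rate: float = 0.01, seed0: int = 0) -> float:
    """Planted-position recovery over independently seeded families.

    For every transfer target (family member that lands in the annotating
    cluster; a rare member whose indels push it below the edge thresholds
    is a singleton and never a target) and every planted root position that
    survives in that member, the transfer is a hit when the predicted
    target coordinate equals the generator's truth coordinate.  Returns
    hits over opportunities, pooled across seeds.
    """
    hits = total = 0
    for s in range(n_seeds):
        recs, truth = fixtures.generate_family(fixtures.FamilySpec(
            seed=seed0 + s, substitution_rate=substitution_rate,
            indel_rate=indel_rate))
        template = recs[0]
        pdb_text, mapping = fixtures.write_toy_pdb(
            template.sequence, sorted(truth[template.accession]), n_metals=2)
        tpl = pdb_sites.build_template(
            pdb_text, "TOY1", "A", template,
            seqmap.load_residue_map(mapping))
        result = pipeline.run_pipeline(recs, [tpl])
        predicted = {
            (t.target_accession, t.target_position)
            for t in result.transferred
            if t.substitution_class != "untransferred"}
        targets = {acc for c in result.clusters if c.is_annotating
                   for acc in c.targets}
        for acc, mapping_ in truth.items():
            if acc not in targets:
                continue
            for root_pos, member_pos in mapping_.items():
                if member_pos == "deleted":
                    continue
                total += 1
                hits += (acc, member_pos) in predicted
    return hits / total if total else float("nan")


def template_rmsd_summary(seed: int = 0, coord_noise: float = 0.5,
                          n_templates: int = 3):
    """Mean/SD pairwise CA RMSD over noisy copies of one synthetic fold.

    Each template is the same helix trace with independent seeded Gaussian
    jitter, so the expected pairwise RMSD is about sqrt(2) x the noise.
    """
    rng = np.random.default_rng(seed)
    seq = fixtures.draw_root(80, (12, 40), rng)
    rec = seqmap.SequenceRecord("SYNT", seq)
    templates, ca_coords, residue_maps = [], {}, {}
    for i in range(n_templates):
        pdb_id = f"SYN{i + 1}"
        pdb_text, mapping = fixtures.write_toy_pdb(
            seq, [12, 40], pdb_id=pdb_id, seed=seed + i,
            coord_noise=coord_noise)
        rmap = seqmap.load_residue_map(mapping)
        templates.append(pdb_sites.build_template(pdb_text, pdb_id, "A",
                                                  rec, rmap))
        ca_coords[pdb_id] = pdb_sites.read_ca_coords(pdb_text, "A")
        residue_maps[pdb_id] = rmap
    from .profile_hmm import build_cluster_msa
    msa = build_cluster_msa([rec], rec)
    mean, sd, pairs = metrics.cluster_rmsd_summary(templates, msa, ca_coords,
                                                   residue_maps)
    return mean, sd, pairs


def null_term_validation_rate(n_replicates: int = 1000, seed: int = 0,
                              alpha: float = 0.01) -> float:
    """Fraction of Bonferroni-validated terms on permuted (null) term tables."""
    rng = np.random.default_rng(seed)
    clusters = [Cluster("C0001", members=[f"A{i}" for i in range(8)]),
                Cluster("C0002", members=[f"B{i}" for i in range(8)])]
    accs = [m for c in clusters for m in c.members] + \
           [f"X{i}" for i in range(24)]
    terms = [f"GO:{i}" for i in range(10)]
    base = pd.DataFrame(
        [(a, t) for a in accs for t in rng.choice(terms, size=3, replace=False)],
        columns=["accession", "term"])
    validated = tested = 0
    for _ in range(n_replicates):
        perm = dict(zip(accs, rng.permutation(accs)))
        null = base.assign(accession=base["accession"].map(perm))
        results = transfer.enrich_clusters(clusters, null, alpha=alpha)
        tested += len(results)
        validated += sum(r.validated for r in results)
    return validated / tested


def rigid_motion_max_rmsd(n_draws: int = 100, seed: int = 0) -> float:
    """Largest residual RMSD of a point set against rigid copies of itself."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    A = rng.normal(size=(10, 3))
    worst = 0.0
    for _ in range(n_draws):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(scale=10.0, size=3)
        worst = max(worst, metrics.kabsch_rmsd(A, A @ R.T + t).rmsd)
    return worst
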
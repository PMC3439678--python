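"""Similarity graph, identity/coverage statistics and components."""

import random

import pytest

from mgsite import blosum, clustering, fixtures
from mgsite.config import Thresholds
from mgsite.seqmap import SequenceRecord


def _rec(acc, seq):
    return SequenceRecord(acc, seq)


class TestPairwiseIdentityCoverage:
    @pytest.mark.parametrize("seq", ["MKVLITDEG", "A", "WWWW"])
    def test_self_comparison(self, seq):
        assert clustering.pairwise_identity_coverage(seq, seq) == (100.0, 100.0)

    def test_prefix_deletion_gives_full_identity_partial_coverage(self):
        random.seed(3)
        full = "".join(random.choices(blosum.AMINO_ACIDS, k=100))
        truncated = full[:90]
        ident, cov = clustering.pairwise_identity_coverage(full, truncated)
        assert ident == pytest.approx(100.0)
        assert cov == pytest.approx(90.0)

    def test_symmetry(self):
        random.seed(11)
        for _ in range(10):
            a = "".join(random.choices(blosum.AMINO_ACIDS, k=random.randint(5, 30)))
            b = "".join(random.choices(blosum.AMINO_ACIDS, k=random.randint(5, 30)))
            assert clustering.pairwise_identity_coverage(a, b) == \
                clustering.pairwise_identity_coverage(b, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_reference_dp(self, seed):
        """Independent plain SW re-implementation agrees on (identity, coverage)."""
        rng = random.Random(200 + seed)
        a = "".join(rng.choices(blosum.AMINO_ACIDS, k=8))
        b = "".join(rng.choices(blosum.AMINO_ACIDS, k=8))
        assert clustering.pairwise_identity_coverage(a, b) == \
            _oracle_identity_coverage(a, b)


def _oracle_identity_coverage(seq_a, seq_b):
    """Straightforward list-based SW with the same conventions."""
    swap = len(seq_b) > len(seq_a) or (len(seq_b) == len(seq_a) and seq_b < seq_a)
    a, b = (seq_b, seq_a) if swap else (seq_a, seq_b)
    go, ge = 11, 1
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {}
    for i in range(n + 1):
        M[i][0] = 0.0
    for j in range(m + 1):
        M[0][j] = 0.0
    best, where = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = [(M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y")]
            src, lab = max(cand, key=lambda t: (t[0], -"MXY".index(t[1])))
            if src <= 0:
                src, lab = 0.0, "S"
            s = src + blosum.score(a[i - 1], b[j - 1])
            if s <= 0:
                s, lab = 0.0, "S"
            M[i][j] = s
            ptr[("M", i, j)] = lab
            xo, xe = M[i - 1][j] - go - ge, X[i - 1][j] - ge
            X[i][j] = max(xo, xe)
            ptr[("X", i, j)] = "M" if xo >= xe else "X"
            yo, ye = M[i][j - 1] - go - ge, Y[i][j - 1] - ge
            Y[i][j] = max(yo, ye)
            ptr[("Y", i, j)] = "M" if yo >= ye else "Y"
            if s > best:
                best, where = s, (i, j)
    if best <= 0:
        return 0.0, 0.0
    i, j = where
    state, cols, ident, a_res = "M", 0, 0, 0
    while True:
        if state == "M":
            cols += 1
            a_res += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            lab = ptr[("M", i, j)]
            i, j = i - 1, j - 1
            if lab == "S":
                break
            state = lab
        elif state == "X":
            cols += 1
            a_res += 1
            state = ptr[("X", i, j)]
            i -= 1
        else:
            cols += 1
            state = ptr[("Y", i, j)]
            j -= 1
    return 100.0 * ident / cols, 100.0 * a_res / len(a)


class TestBuildGraph:
    def test_identical_duplicates_connected(self):
        recs = [_rec("A", "MKVLITDEGSAD" * 3), _rec("B", "MKVLITDEGSAD" * 3)]
        edges = clustering.build_graph(recs)
        assert len(edges) == 1
        e = edges[0]
        assert (e.accession_a, e.accession_b) == ("A", "B")
        assert e.identity == 100.0 and e.coverage == 100.0

    def test_threshold_is_inclusive_at_forty(self):
        th = Thresholds(min_identity=40, min_coverage=90)
        # two sequences engineered at exactly 40% identity over full coverage:
        # 4 of 10 aligned residues identical, no gaps
        a = "DDDDWWWWWW"
        b = "DDDDYYYYYY"
        ident, cov = clustering.pairwise_identity_coverage(a, b)
        assert ident == pytest.approx(40.0)
        edges = clustering.build_graph([_rec("A", a), _rec("B", b)], th)
        assert len(edges) == 1

    def test_below_threshold_excluded(self):
        th = Thresholds(min_identity=40, min_coverage=90)
        a = "DDDWWWWWWW"  # 30% identity
        b = "DDDYYYYYYY"
        edges = clustering.build_graph([_rec("A", a), _rec("B", b)], th)
        assert edges == []

    def test_three_families_cluster_apart(self):
        records, _, assignment = fixtures.three_family_records(seed=5)
        edges = clustering.build_graph(records)
        for e in edges:
            assert assignment[e.accession_a] == assignment[e.accession_b]


def _bfs_components(nodes, edge_pairs):
    adj = {n: set() for n in nodes}
    for a, b in edge_pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        queue, comp = [n], set()
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestConnectedComponents:
    def test_no_edges_all_singletons(self):
        clusters, singletons = clustering.connected_components("ABCDE", [])
        assert clusters == [] and singletons == list("ABCDE")

    def test_transitive_chain_forms_one_cluster(self):
        edges = [clustering.SimilarityEdge("A", "B", 50, 95),
                 clustering.SimilarityEdge("B", "C", 50, 95)]
        clusters, singletons = clustering.connected_components("ABC", edges)
        assert len(clusters) == 1 and clusters[0].members == ["A", "B", "C"]
        assert singletons == []

    def test_unknown_node_rejected(self):
        edges = [clustering.SimilarityEdge("A", "Z", 50, 95)]
        with pytest.raises(ValueError, match="unknown node"):
            clustering.connected_components("AB", edges)

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    def test_partition_matches_bfs_oracle_on_random_graphs(self, p):
        rng = random.Random(int(p * 1000))
        for trial in range(67):
            n = rng.randint(2, 50)
            nodes = [f"N{i:02d}" for i in range(n)]
            pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                     if rng.random() < p]
            edges = [clustering.SimilarityEdge(a, b, 50, 95) for a, b in pairs]
            clusters, singletons = clustering.connected_components(nodes, edges)
            ours = {frozenset(c.members) for c in clusters} | \
                   {frozenset({s}) for s in singletons}
            assert ours == _bfs_components(nodes, pairs)
            # partition property: every node exactly once
            flat = [m for c in clusters for m in c.members] + singletons
            assert sorted(flat) == sorted(nodes)

    def test_monotonicity_edge_removal_refines_partition(self):
        rng = random.Random(42)
        nodes = [f"N{i:02d}" for i in range(20)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if rng.random() < 0.15]
        edges = [clustering.SimilarityEdge(a, b, 50 + 40 * rng.random(), 95)
                 for a, b in pairs]
        loose, _ = clustering.connected_components(nodes, edges)
        strict_edges = [e for e in edges if e.identity >= 70]
        strict, strict_singles = clustering.connected_components(nodes, strict_edges)
        comp_of = {m: i for i, c in enumerate(loose) for m in c.members}
        for c in strict:  # each strict cluster sits inside one loose cluster
            assert len({comp_of.get(m) for m in c.members}) == 1


class TestAttachTemplates:
    def _tpl(self, acc):
        from mgsite.pdb_sites import MetalSite, TemplateStructure
        site = MetalSite(pdb_id="1AAA", chain="A", metal_instance=301,
                         coordinating_positions=[(5, "D")])
        return TemplateStructure(pdb_id="1AAA", chain="A", accession=acc,
                                 observed_positions=set(), coverage=1.0,
                                 sites=[site])

    def test_template_inside_component_flags_cluster(self):
        edges = [clustering.SimilarityEdge(a, b, 60, 95)
                 for a, b in [("P1", "P2"), ("P2", "P3"), ("P3", "P4")]]
        clusters, singles = clustering.connected_components(
            ["P1", "P2", "P3", "P4"], edges)
        annotating = clustering.attach_templates(clusters, singles, [self._tpl("P2")])
        assert len(annotating) == 1
        assert annotating[0].targets == ["P1", "P3", "P4"]

    def test_singleton_template_annotates_nothing(self):
        clusters, singles = clustering.connected_components(["P1", "P2"], [])
        with pytest.warns(UserWarning, match="singleton"):
            annotating = clustering.attach_templates(clusters, singles,
                                                     [self._tpl("P1")])
        assert annotating == []

    def test_two_templates_both_attached(self):
        edges = [clustering.SimilarityEdge("P1", "P2", 60, 95)]
        clusters, singles = clustering.connected_components(["P1", "P2"], edges)
        tpls = [self._tpl("P1"), self._tpl("P2")]
        annotating = clustering.attach_templates(clusters, singles, tpls)
        assert len(annotating) == 1
        assert sorted(annotating[0].templates) == ["P1", "P2"]
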
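"""ORF calling, protein clustering, network construction, communities."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import ventmge as v
from oracles import all_partitions, modularity, nw_affine_identity_coverage, oracle_orfs
from ventmge.selection import CompletenessCall
from ventmge.seqs import random_dna, revcomp

AA = "ACDEFGHIKLMNPQRSTVWY"


def _gene(rng, n_codons=80) -> str:
    """ATG + n non-stop codons + TAA."""
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
    body = "".join(sense[int(rng.integers(len(sense)))] for _ in range(n_codons))
    return "ATG" + body + "TAA"


class TestCallOrfs:
    def test_constructed_forward_orf(self, rng):
        gene = _gene(rng, 80)
        contig = "CCCC" + "TAA" + gene + "CCCC"
        orfs = [o for o in v.call_orfs(contig, "c") if o.strand == "+"]
        assert len(orfs) >= 1
        o = orfs[0]
        assert (o.start, o.end) == (7, 7 + len(gene))
        assert len(o.protein) == 81
        assert o.protein.startswith("M")
        assert "*" not in o.protein

    def test_strand_closure(self, rng):
        gene = _gene(rng, 90)
        fwd_contig = "CC" + "TAA" + gene + "GG"
        rev_contig = revcomp(fwd_contig)
        fwd = v.call_orfs(fwd_contig, "c")
        rev = v.call_orfs(rev_contig, "c")
        f = [o for o in fwd if o.strand == "+"][0]
        r = [o for o in rev if o.strand == "-"][0]
        assert r.protein == f.protein
        n = len(fwd_contig)
        assert (r.start, r.end) == (n - f.end, n - f.start)

    def test_equals_sixframe_bruteforce_on_random_contigs(self):
        """Vectorized scan equals the plain six-frame enumerator, and every
        reported ORF re-verifies (start codon, in-frame stop, no internal
        stop) on seeded random 10 kbp contigs."""
        stops = {"TAA", "TAG", "TGA"}
        starts = {"ATG", "GTG", "TTG"}
        rng = np.random.default_rng(23)
        for _ in range(8):
            contig = random_dna(rng, 10_000)
            orfs = v.call_orfs(contig, "c")
            got = sorted((o.start, o.end, o.strand) for o in orfs)
            assert got == oracle_orfs(contig)
            for o in orfs:
                nt = contig[o.start : o.end]
                if o.strand == "-":
                    nt = revcomp(nt)
                assert nt[:3] in starts and nt[-3:] in stops
                codons = {nt[i : i + 3] for i in range(0, len(nt) - 3, 3)}
                assert not codons & stops
                assert len(o.protein) == (o.end - o.start) // 3 - 1 >= 60

    def test_n_codons_never_start_or_stop(self):
        contig = "NTGAAA" * 100  # NTG is not a start; no real ORF material
        assert v.call_orfs(contig, "c") == []


class TestClusterProteins:
    def _protein(self, rng, n=120):
        return "M" + "".join(AA[int(rng.integers(20))] for _ in range(n - 1))

    def _diverge(self, rng, prot, frac):
        chars = list(prot)
        for pos in rng.choice(len(prot) - 1, size=int(frac * (len(prot) - 1)), replace=False) + 1:
            chars[pos] = AA[int(rng.integers(20))]
        return "".join(chars)

    def test_identical_proteins_one_cluster(self, rng):
        p = self._protein(rng)
        clusters = v.cluster_proteins([("a", p), ("b", p)])
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b"]

    def test_moderate_divergence_together_random_apart(self, rng):
        """~65%- and ~35%-identity homolog pairs cluster together; an
        unrelated pair does not; outcomes re-verified by an independent
        affine-gap DP."""
        p = self._protein(rng, 150)
        near = self._diverge(rng, p, 0.35)
        twilight = self._diverge(rng, p, 0.65)  # ~35% site identity
        far = self._protein(rng, 150)
        clusters = v.cluster_proteins(
            [("p", p), ("near", near), ("twilight", twilight), ("far", far)]
        )
        assign = {m: c.cluster_id for c in clusters for m in c.members}
        assert assign["p"] == assign["near"] == assign["twilight"]
        assert assign["far"] != assign["p"]
        ident_near, ca, cb = nw_affine_identity_coverage(p, near)
        assert ident_near >= 0.25 and ca >= 0.80 and cb >= 0.80
        ident_tw, _, _ = nw_affine_identity_coverage(p, twilight)
        assert ident_tw >= 0.25
        ident_far, _, _ = nw_affine_identity_coverage(p, far)
        assert ident_far < 0.25

    def test_members_reverify_against_representative(self, rng):
        """Cluster soundness: every member aligns to its representative at
        >= 25% identity and >= 80% bidirectional coverage under an
        independent DP (small slack for co-optimal alignment paths)."""
        base = [self._protein(rng, int(rng.integers(80, 160))) for _ in range(6)]
        prots = [(f"o{i}{j}", self._diverge(rng, b, rng.uniform(0, 0.4)))
                 for i, b in enumerate(base) for j in range(3)]
        clusters = v.cluster_proteins(prots)
        seqs = dict(prots)
        for c in clusters:
            for m in c.members:
                if m == c.representative:
                    continue
                ident, ca, cb = nw_affine_identity_coverage(seqs[c.representative], seqs[m])
                assert ident >= 0.25 - 0.03
                assert ca >= 0.80 - 0.03 and cb >= 0.80 - 0.03

    def test_short_protein_cannot_cover_long_one(self, rng):
        p = self._protein(rng, 200)
        clusters = v.cluster_proteins([("long", p), ("short", p[:100])])
        assert len(clusters) == 2

    def test_empty_input(self):
        assert v.cluster_proteins([]) == []

    def test_deterministic(self, rng):
        prots = [(f"p{i}", self._protein(rng, int(rng.integers(70, 150)))) for i in range(10)]
        a = v.cluster_proteins(prots)
        b = v.cluster_proteins(list(prots))
        assert [(c.cluster_id, c.members) for c in a] == [(c.cluster_id, c.members) for c in b]


class TestNetwork:
    def test_exactly_five_shared_clusters_make_an_edge(self):
        cc = {"a": [f"pc{i}" for i in range(5)], "b": [f"pc{i}" for i in range(5)]}
        g = v.build_network(cc).graph
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["shared"] == 5
        assert g.edges["a", "b"]["weight"] == 5

    def test_four_shared_clusters_no_edge(self):
        cc = {"a": [f"pc{i}" for i in range(4)], "b": [f"pc{i}" for i in range(4)] + ["x"]}
        g = v.build_network(cc).graph
        assert not g.has_edge("a", "b")
        assert set(g.nodes) == {"a", "b"}  # isolated nodes retained

    def test_multicopy_cluster_weight(self):
        shared = [f"pc{i}" for i in range(5)]
        cc = {"a": shared + ["pc0"], "b": shared + ["pc0", "y"]}
        g = v.build_network(cc).graph
        assert g.edges["a", "b"]["shared"] == 5
        assert g.edges["a", "b"]["weight"] == 6  # pc0 counted min(2,2)=2


class TestCommunities:
    def _clique_pair(self, k):
        g = nx.Graph()
        left = [f"L{i}" for i in range(k)]
        right = [f"R{i}" for i in range(k)]
        for grp in (left, right):
            for i in range(k):
                for j in range(i + 1, k):
                    g.add_edge(grp[i], grp[j], weight=1, shared=5)
        g.add_edge(left[0], right[0], weight=1, shared=5)
        return g, left, right

    def test_two_cliques_split_and_match_exhaustive_modularity(self):
        """Louvain recovers the two cliques; exhaustive enumeration over all
        set partitions of the 8-node graph confirms that split is the
        modularity optimum."""
        g, left, right = self._clique_pair(4)
        gsg = v.GeneSharingGraph(graph=g, contig_clusters={})
        labels = v.detect_communities(gsg, seed=0)
        assert len(set(labels.values())) == 2
        assert len({labels[n] for n in left}) == 1
        assert len({labels[n] for n in right}) == 1
        best = max(all_partitions(sorted(g.nodes)), key=lambda p: modularity(g, p))
        assert sorted(map(sorted, best)) == [sorted(left), sorted(right)]

    def test_two_six_cliques(self):
        g, left, right = self._clique_pair(6)
        labels = v.detect_communities(v.GeneSharingGraph(graph=g, contig_clusters={}), seed=0)
        assert sorted(map(sorted, {frozenset(n for n in labels if labels[n] == c)
                                   for c in set(labels.values())})) == [sorted(left), sorted(right)]

    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        labels = v.detect_communities(v.GeneSharingGraph(graph=g, contig_clusters={}), seed=0)
        assert sorted(labels.values()) == [0, 1, 2, 3]

    def test_seeded_determinism(self):
        g, _l, _r = self._clique_pair(5)
        a = v.detect_communities(v.GeneSharingGraph(graph=g, contig_clusters={}), seed=4)
        b = v.detect_communities(v.GeneSharingGraph(graph=g, contig_clusters={}), seed=4)
        assert a == b


class TestCommunitySummaries:
    CC = {
        "m1": ["core", "x1"],
        "m2": ["core", "x2"],
        "m3": ["core", "x3"],
        "m4": ["core"],
        "m5": ["other"],
    }

    def test_core_cluster_prevalence(self):
        members = list(self.CC)
        core = v.core_clusters(members, self.CC, min_frac=0.80)
        assert core == ["core"]  # 4/5 = 0.8 passes; "other" at 1/5 does not

    def test_below_threshold_not_core(self):
        members = ["m1", "m2", "m3", "m4", "m5"]
        cc = dict(self.CC)
        cc["m4"] = ["x4"]  # core now in 3/5 = 0.6 < 0.8
        assert "core" not in v.core_clusters(members, cc, min_frac=0.80)

    def test_zero_threshold_returns_all(self):
        assert set(v.core_clusters(["m1", "m5"], self.CC, min_frac=0.0)) == {"core", "x1", "other"}

    def test_representative_seventyfive_percent_rule(self):
        lengths = {"a": 20_000, "b": 24_000, "c": 15_000, "d": 14_900}
        comp = {
            "a": CompletenessCall("a", "DTR", 30),
            "b": CompletenessCall("b", "ITR", 25),
        }
        reps, flag = v.select_representatives(list(lengths), lengths, comp)
        assert flag is True
        assert "c" in reps        # 15,000 >= 0.75 * 20,000
        assert "d" not in reps    # 14,900 < 15,000
        assert {"a", "b"} <= set(reps)

    def test_no_complete_member_flags_community(self):
        lengths = {"a": 9000, "b": 8000}
        reps, flag = v.select_representatives(["a", "b"], lengths, {})
        assert reps == [] and flag is False

    def test_targeting_density(self):
        hits = [
            v.ProtospacerHit(f"sp{i}", "c", 10 * i, 10 * i + 37, "+", 0, 1.0) for i in range(7)
        ]
        assert v.targeting_density(2000, hits) == pytest.approx(3.5)
        twice = hits + [hits[0]]
        assert v.targeting_density(2000, twice) == pytest.approx(3.5)
        assert v.targeting_density(2000, []) == 0.0
        with pytest.raises(ValueError):
            v.targeting_density(0, hits)
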
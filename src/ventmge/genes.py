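"""ORF calling, protein clustering, and the contig gene-sharing network.

ORFs are called by a deterministic six-frame longest-ORF scan (translation
table 11), proteins are clustered by greedy incremental global alignment at
25% identity / 80% bidirectional coverage, and contigs become nodes of a
network whose edges connect contigs sharing at least five protein clusters,
weighted by the total number of shared genes.  Seeded weighted-modularity
(Louvain) community detection over this network approximates MGE families;
per-community core clusters, representative genomes (the 75%-of-shortest-
complete-genome rule) and spacer-targeting densities summarise each family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .protospacers import ProtospacerHit
from .selection import CompletenessCall
from .seqs import encode

_START = {"ATG", "GTG", "TTG"}
_STOP = {"TAA", "TAG", "TGA"}
# codon codes (A=0,C=1,G=2,T=3 base-4) for vectorized scanning
_START_CODES = {0 * 16 + 3 * 4 + 2, 2 * 16 + 3 * 4 + 2, 3 * 16 + 3 * 4 + 2}
_STOP_CODES = {3 * 16 + 0 * 4 + 0, 3 * 16 + 0 * 4 + 2, 3 * 16 + 2 * 4 + 0}


@dataclass
class OrfRecord:
    """A called open reading frame (forward-strand half-open nt coordinates)."""

    orf_id: str
    contig_id: str
    start: int
    end: int  # includes the stop codon
    strand: str
    frame: int
    protein: str


@dataclass
class ProteinCluster:
    cluster_id: str
    representative: str  # orf id
    members: list[str]


@dataclass
class GeneSharingGraph:
    """Contigs as nodes, shared-protein-cluster edges, community labels."""

    graph: nx.Graph
    contig_clusters: dict[str, list[str]]  # cluster multiset per contig
    communities: dict[str, int] = field(default_factory=dict)


def _translate(nt: str) -> str:
    """Translate a gene with table 11, forcing M at the start codon."""
    prot = str(Seq(nt).translate(table=11))
    return "M" + prot[1:]


def call_orfs(contig: str, contig_id: str = "", min_aa: int = 60) -> list[OrfRecord]:
    """Six-frame ORF scan: start codon to next in-frame stop, table 11.

    Per (strand, frame, stop codon) only the longest ORF (earliest start) is
    reported; ORFs without a stop codon are not.  Codons containing N never
    act as start or stop.  Coordinates are always on the forward strand.
    """
    n = len(contig)
    out: list[OrfRecord] = []
    from .seqs import revcomp

    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        enc = encode(seq).astype(np.int64)
        for frame in range(3):
            n_codons = (n - frame) // 3
            if n_codons < min_aa + 1:
                continue
            c0 = enc[frame : frame + 3 * n_codons : 3]
            c1 = enc[frame + 1 : frame + 1 + 3 * n_codons : 3]
            c2 = enc[frame + 2 : frame + 2 + 3 * n_codons : 3]
            ok = (c0 < 4) & (c1 < 4) & (c2 < 4)
            codes = np.where(ok, c0 * 16 + c1 * 4 + c2, -1)
            stop_idx = np.flatnonzero(np.isin(codes, list(_STOP_CODES)))
            start_idx = np.flatnonzero(np.isin(codes, list(_START_CODES)))
            seg_start = 0
            for st in stop_idx:
                # earliest start codon in [seg_start, st)
                j = int(np.searchsorted(start_idx, seg_start, side="left"))
                if j < len(start_idx) and start_idx[j] < st:
                    s_codon = int(start_idx[j])
                    aa_len = int(st) - s_codon
                    if aa_len >= min_aa:
                        nt_start = frame + 3 * s_codon
                        nt_end = frame + 3 * (int(st) + 1)
                        prot = _translate(seq[nt_start:nt_end-3])
                        if strand == "+":
                            f_start, f_end = nt_start, nt_end
                        else:
                            f_start, f_end = n - nt_end, n - nt_start
                        out.append(
                            OrfRecord(
                                orf_id="",
                                contig_id=contig_id,
                                start=f_start,
                                end=f_end,
                                strand=strand,
                                frame=frame,
                                protein=prot,
                            )
                        )
                seg_start = int(st) + 1
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    for i, o in enumerate(out):
        o.orf_id = f"{contig_id}_orf{i:03d}" if contig_id else f"orf{i:03d}"
    return out


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def alignment_stats(
    aligner: PairwiseAligner, a: str, b: str
) -> tuple[float, float, float, float]:
    """(identity, coverage_a, coverage_b, score) of one global alignment.

    Identity is identical columns over all alignment columns (gaps
    included); coverage of a sequence is the fraction of its residues that
    sit in residue-to-residue columns.
    """
    aln = aligner.align(a, b)[0]
    a_segs, b_segs = aln.aligned
    identities = 0
    aligned_res = 0
    for (ta, tb), (qa, qb) in zip(a_segs, b_segs):
        aligned_res += tb - ta
        identities += sum(x == y for x, y in zip(a[ta:tb], b[qa:qb]))
    # every gap column consumes one residue, every aligned column two
    columns = len(a) + len(b) - aligned_res
    identity = identities / columns if columns else 0.0
    return identity, aligned_res / len(a), aligned_res / len(b), float(aln.score)


def alignment_identity_coverage(
    aligner: PairwiseAligner, a: str, b: str
) -> tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) of one global BLOSUM62 alignment."""
    ident, cov_a, cov_b, _score = alignment_stats(aligner, a, b)
    return ident, cov_a, cov_b


def cluster_proteins(
    proteins: list[tuple[str, str]],
    min_identity: float = 0.25,
    min_cov: float = 0.80,
) -> list[ProteinCluster]:
    """Greedy incremental clustering of proteins at >= 25% identity.

    ``proteins`` is a list of (orf_id, amino-acid sequence).  Proteins are
    visited by descending length (ties lexicographic by sequence then id);
    each is compared to every existing cluster representative by global
    alignment (BLOSUM62, gap open 11 / extend 1) and joins the
    HIGHEST-identity cluster meeting the identity threshold with >= min_cov
    coverage of BOTH sequences and a positive alignment score (ties to the
    earliest-founded cluster), else founds a new cluster.  Two guards beyond
    the raw identity/coverage thresholds keep spurious joins out: best-hit
    rather than first-hit assignment, and the positive-score homology gate —
    unrelated proteins occasionally reach 25% column identity, but their
    global BLOSUM62 scores stay negative (random columns score below zero
    on average), whereas genuinely homologous pairs score far above.
    Deterministic for a given input set.
    """
    aligner = _make_aligner()
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[1], p[0]))
    clusters: list[ProteinCluster] = []
    reps: list[tuple[str, str]] = []
    for orf_id, seq in order:
        best_ident = -1.0
        best_ci = -1
        for ci, (_rep_id, rep_seq) in enumerate(reps):
            # coverage of the longer sequence can never exceed len_short/len_long
            if len(seq) < min_cov * len(rep_seq) - 1e-9:
                continue
            ident, cov_r, cov_q, score = alignment_stats(aligner, rep_seq, seq)
            if (
                ident >= min_identity - 1e-12
                and cov_r >= min_cov - 1e-12
                and cov_q >= min_cov - 1e-12
                and score > 0.0
                and ident > best_ident + 1e-15
            ):
                best_ident = ident
                best_ci = ci
        if best_ci >= 0:
            clusters[best_ci].members.append(orf_id)
        else:
            clusters.append(ProteinCluster(f"pc{len(clusters):04d}", orf_id, [orf_id]))
            reps.append((orf_id, seq))
    return clusters


def build_network(
    contig_clusters: dict[str, list[str]], min_shared: int = 5
) -> GeneSharingGraph:
    """Build the gene-sharing network from per-contig cluster multisets.

    An edge connects two contigs sharing >= min_shared distinct clusters;
    its weight is the total number of shared genes,
    sum_c min(count_i(c), count_j(c)).  Contigs without qualifying partners
    remain as isolated nodes.
    """
    g = nx.Graph()
    ids = sorted(contig_clusters)
    g.add_nodes_from(ids)
    counts = {
        cid: {c: clusters.count(c) for c in set(clusters)}
        for cid, clusters in contig_clusters.items()
    }
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = set(counts[a]) & set(counts[b])
            if len(shared) >= min_shared:
                weight = sum(min(counts[a][c], counts[b][c]) for c in shared)
                g.add_edge(a, b, shared=len(shared), weight=weight)
    return GeneSharingGraph(graph=g, contig_clusters=dict(contig_clusters))


def detect_communities(gsg: GeneSharingGraph, seed: int = 0) -> dict[str, int]:
    """Non-overlapping communities by seeded weighted modularity (Louvain).

    Labels are dense integers ordered by each community's smallest node id;
    isolated nodes get singleton communities.  Deterministic for a fixed
    seed and input graph.
    """
    g = gsg.graph
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = {node: i for i, members in enumerate(comms) for node in members}
    gsg.communities = labels
    return labels


def core_clusters(
    members: list[str],
    contig_clusters: dict[str, list[str]],
    min_frac: float = 0.80,
) -> list[str]:
    """Clusters present in at least min_frac of a community's members.

    Returned sorted by descending prevalence (ties by cluster id).
    """
    if not members:
        raise ValueError("community has no members")
    prevalence: dict[str, int] = {}
    for m in members:
        for c in set(contig_clusters.get(m, [])):
            prevalence[c] = prevalence.get(c, 0) + 1
    n = len(members)
    keep = [(c, k / n) for c, k in prevalence.items() if k / n >= min_frac - 1e-12]
    keep.sort(key=lambda x: (-x[1], x[0]))
    return [c for c, _f in keep]


def select_representatives(
    members: list[str],
    lengths: dict[str, int],
    completeness_calls: dict[str, CompletenessCall],
    min_frac: float = 0.75,
) -> tuple[list[str], bool]:
    """Representative members: >= min_frac of the shortest complete genome.

    Returns (representative ids, has_complete_genome).  When no member is
    complete the list is empty and the flag is False — such communities
    cannot anchor a genome-length estimate.
    """
    complete_lengths = [
        lengths[m]
        for m in members
        if completeness_calls.get(m, CompletenessCall(m, "none")).is_complete
    ]
    if not complete_lengths:
        return [], False
    l_star = min(complete_lengths)
    reps = sorted(m for m in members if lengths[m] >= min_frac * l_star - 1e-9)
    return reps, True


def targeting_density(contig_length: int, hits: list[ProtospacerHit]) -> float:
    """Distinct spacers matching a contig per kilobase of contig."""
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    distinct = len({h.spacer_id for h in hits})
    return distinct / (contig_length / 1000.0)
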
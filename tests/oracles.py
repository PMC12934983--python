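"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by a strategy independent of the
implementation under test: exhaustive pairwise shift comparison instead of
k-mer hashing (arrays), full sliding-window scans instead of seeded lookup
(protospacers, terminal repeats), whole-sequence dynamic programming instead
of anchor chaining (ANI), and plain six-frame loops instead of vectorized
codon scanning (ORFs).
"""

from __future__ import annotations

import itertools

import edlib
import numpy as np

from ventmge.arrays import DetectParams
from ventmge.seqs import encode, revcomp

# --------------------------------------------------------------------------
# CRISPR arrays: exhaustive periodic-repeat enumeration
# --------------------------------------------------------------------------


def _oracle_grow(seq: str, anchors: list[int], k: int, params: DetectParams):
    """Pure-Python re-implementation of the window growth/trim semantics."""
    n = len(seq)
    m = len(anchors)
    cap = params.max_repeat_len + 2 * params.max_divergence

    def column(off):
        bases = []
        for p in anchors:
            i = p + off
            if i < 0 or i >= n:
                return None
            bases.append(seq[i])
        counts = {}
        for b in bases:
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            return None
        best = max(counts.values())
        cons = sorted(b for b, c in counts.items() if c == best)[0]
        mism = [b != cons or b not in "ACGT" for b in bases]
        acgt = [b in "ACGT" for b in bases]
        return mism, not any(mism), acgt

    cost = [0] * m
    cols = {off: ([False] * m, True) for off in range(k)}
    l, r = 0, k
    for direction in (+1, -1):
        nrun = [0] * m
        while r - l < cap:
            off = r if direction == +1 else l - 1
            info = column(off)
            if info is None:
                break
            mism, unan, acgt = info
            nxt = [0 if a else c + 1 for a, c in zip(acgt, nrun)]
            if any(c > 2 for c in nxt):
                break
            if any(c + int(d) > params.max_divergence for c, d in zip(cost, mism)):
                break
            cost = [c + int(d) for c, d in zip(cost, mism)]
            cols[off] = (mism, unan)
            nrun = nxt
            if direction == +1:
                r += 1
            else:
                l -= 1
    while r > l and not cols[r - 1][1]:
        cost = [c - int(d) for c, d in zip(cost, cols[r - 1][0])]
        r -= 1
    while r > l and not cols[l][1]:
        cost = [c - int(d) for c, d in zip(cost, cols[l][0])]
        l += 1
    if r <= l:
        return None
    return l, r, cost


def oracle_detect_arrays(seq: str, params: DetectParams | None = None):
    """Brute-force periodic-repeat enumerator.

    Candidate anchors come from exhaustively comparing every position pair
    at every admissible period (no hashing); growth, validation and overlap
    resolution follow the same declared semantics as the detector.  Returns
    a list of (instance_starts, repeat_len) sorted by position.
    """
    params = params or DetectParams()
    k = params.seed_k
    enc = encode(seq)
    n = len(enc)
    acgt_ok = np.convolve((enc < 4).astype(int), np.ones(k, dtype=int), mode="valid") == k

    edges: dict[int, list[int]] = {}
    nodes: set[int] = set()
    for d in range(params.min_gap, params.max_gap + 1):
        if d + k > n:
            break
        eq = (enc[:-d] == enc[d:]) & (enc[:-d] < 4)
        run = np.convolve(eq.astype(int), np.ones(k, dtype=int), mode="valid") == k
        for i in np.flatnonzero(run):
            i = int(i)
            if acgt_ok[i] and i + d < len(acgt_ok) and acgt_ok[i + d]:
                edges.setdefault(i, []).append(i + d)
                nodes.add(i)
                nodes.add(i + d)

    # seed k-mers recurring at sub-period spacing anywhere in the sequence
    # are ambiguous tandem seeds: drop every edge of such a k-mer (string
    # scanning here, independent of the detector's code grouping)
    ambiguous: set[str] = set()
    for i in sorted(nodes):
        kmer = seq[i : i + k]
        if kmer in ambiguous:
            continue
        occ = []
        p = seq.find(kmer)
        while p != -1:
            occ.append(p)
            p = seq.find(kmer, p + 1)
        if any(b - a < params.min_gap for a, b in zip(occ, occ[1:])):
            ambiguous.add(kmer)
    if ambiguous:
        nodes = {i for i in nodes if seq[i : i + k] not in ambiguous}
        edges = {
            i: [j for j in succ if j in nodes]
            for i, succ in edges.items()
            if i in nodes
        }
        edges = {i: s for i, s in edges.items() if s}

    has_pred = {j for succ in edges.values() for j in succ}
    paths: list[list[int]] = []

    def walk(path: list[int]) -> None:
        succ = edges.get(path[-1], [])
        if not succ:
            if len(path) >= params.min_repeats:
                paths.append(path)
            return
        for j in succ:
            walk(path + [j])

    for start in sorted(nodes - has_pred):
        walk([start])

    candidates = []
    for anchors in paths:
        grown = _oracle_grow(seq, anchors, k, params)
        if grown is None:
            continue
        l, r, cost = grown
        rep_len = r - l
        if not params.min_repeat_len <= rep_len <= params.max_repeat_len:
            continue
        if any(c > params.max_divergence for c in cost):
            continue
        if any(
            not params.min_spacer_len <= (b + l) - (a + r) <= params.max_spacer_len
            for a, b in zip(anchors, anchors[1:])
        ):
            continue
        inst = tuple(p + l for p in anchors)
        candidates.append((inst, rep_len, inst[-1] + rep_len))

    uniq = sorted(set(candidates), key=lambda c: (-len(c[0]), -(c[2] - c[0][0]), c[0][0], c[0]))
    accepted = []
    for cand in uniq:
        s, e = cand[0][0], cand[2]
        if all(e <= s0 or s >= e0 for (s0, e0) in ((a[0][0], a[2]) for a in accepted)):
            accepted.append(cand)
    return sorted((inst, rep_len) for inst, rep_len, _e in accepted)


def oracle_anchor(repeat: str, references: list[tuple[str, str]], max_mm: int = 1):
    """Exhaustive Hamming anchor over repeat x reference x orientation."""
    best = None
    for idx, (rid, ref) in enumerate(references):
        if len(ref) != len(repeat):
            continue
        for rank, query in enumerate((repeat, revcomp(repeat))):
            d = sum(a != b for a, b in zip(query, ref))
            if d <= max_mm and (best is None or (d, idx, rank) < best[0]):
                best = ((d, idx, rank), rid, "+-"[rank], d)
    return None if best is None else best[1:]


# --------------------------------------------------------------------------
# protospacer search: exhaustive all-position, both-strand scan
# --------------------------------------------------------------------------


def oracle_search(spacer_seq: str, contigs: dict[str, str], min_identity: float = 0.90):
    """All (contig, position, strand) full-length matches of one spacer."""
    L = len(spacer_seq)
    m_max = int(np.floor((1.0 - min_identity) * L + 1e-9))
    out = []
    for cid, seq in contigs.items():
        enc = encode(seq)
        if len(enc) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        for strand, oriented in (("+", spacer_seq), ("-", revcomp(spacer_seq))):
            q = encode(oriented)
            mm = np.count_nonzero((win != q) | (win > 3) | (q > 3)[None, :], axis=1)
            for pos in np.flatnonzero(mm <= m_max):
                out.append((cid, int(pos), strand, int(mm[pos])))
    return sorted(out)


# --------------------------------------------------------------------------
# terminal repeats: direct end-overlap scan over every length
# --------------------------------------------------------------------------


def oracle_terminal_repeat(seq: str, min_len: int = 20, frac: float = 0.10, window: int = 2000):
    """Longest end-anchored DTR/ITR by scanning every admissible length."""
    n = len(seq)
    if n < 2 * min_len:
        return ("none", 0, 0)
    limit = min(window, n // 2)
    best = ("none", 0, 0)
    for L in range(limit, min_len - 1, -1):
        pre, suf = seq[:L], seq[n - L:]
        mm = sum(a != b or a not in "ACGT" for a, b in zip(pre, suf))
        if mm <= frac * L + 1e-9:
            best = ("DTR", L, mm)
            break
    for L in range(limit, min_len - 1, -1):
        if best[0] == "DTR" and L <= best[1]:
            break
        pre, suf = seq[:L], revcomp(seq[n - L:])
        mm = sum(a != b or a not in "ACGT" for a, b in zip(pre, suf))
        if mm <= frac * L + 1e-9:
            best = ("ITR", L, mm)
            break
    return best


# --------------------------------------------------------------------------
# alignment oracles
# --------------------------------------------------------------------------


def edlib_global_identity(a: str, b: str) -> float:
    """Identity of a full dynamic-programming global alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matched = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            run = int(num)
            num = ""
            cols += run
            if ch == "=":
                matched += run
    return matched / cols


_BLOSUM62 = None


def nw_affine_identity_coverage(a: str, b: str) -> tuple[float, float, float]:
    """Independent affine-gap global DP (BLOSUM62, open 11 / extend 1).

    Returns (identity over alignment columns, coverage of a, coverage of b),
    with coverage = residues in residue-to-residue columns / length.
    """
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    sub = _BLOSUM62
    la, lb = len(a), len(b)
    NEG = -1e9
    open_, ext = -11.0, -1.0
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (a consumed)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = open_ + ext * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = open_ + ext * (j - 1)
    for i in range(1, la + 1):
        srow = sub[a[i - 1]]
        for j in range(1, lb + 1):
            s = srow[b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ident = aligned = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            aligned += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            # choose predecessor consistent with the affine recurrence
            if abs(X[i, j] - (X[i - 1, j] + ext)) < 1e-6:
                prev = 1
            elif abs(X[i, j] - (M[i - 1, j] + open_)) < 1e-6:
                prev = 0
            else:
                prev = 2
            i -= 1
            state = prev
        else:
            if abs(Y[i, j] - (Y[i, j - 1] + ext)) < 1e-6:
                prev = 2
            elif abs(Y[i, j] - (M[i, j - 1] + open_)) < 1e-6:
                prev = 0
            else:
                prev = 1
            j -= 1
            state = prev
    return ident / cols, aligned / la, aligned / lb


# --------------------------------------------------------------------------
# ORFs: plain six-frame loop
# --------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG", "TTG"}


def oracle_orfs(seq: str, min_aa: int = 60):
    """Brute-force six-frame ORF enumeration: (start, end, strand) triples."""
    n = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            seg_start = 0
            for ci, codon in enumerate(codons):
                if codon in _STOPS:
                    starts = [
                        j for j in range(seg_start, ci)
                        if codons[j] in _STARTS and all(b in "ACGT" for b in codons[j])
                    ]
                    if starts and ci - starts[0] >= min_aa:
                        nt_s = frame + 3 * starts[0]
                        nt_e = frame + 3 * (ci + 1)
                        if strand == "+":
                            out.append((nt_s, nt_e, "+"))
                        else:
                            out.append((n - nt_e, n - nt_s, "-"))
                    seg_start = ci + 1
    return sorted(out)


# --------------------------------------------------------------------------
# dereplication and communities
# --------------------------------------------------------------------------


def oracle_greedy_dedup(sequences: dict[str, str], ani_fn, min_ani=0.98, min_cov=0.95):
    """Brute-force greedy cluster assignment under the documented order."""
    order = sorted(sequences, key=lambda c: (-len(sequences[c]), c))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for cid in order:
        for rep in reps:
            ani, cov, _ = ani_fn(sequences[rep], sequences[cid])
            if ani >= min_ani - 1e-12 and cov >= min_cov - 1e-12:
                assign[cid] = rep
                break
        else:
            reps.append(cid)
            assign[cid] = cid
    return assign


def all_partitions(items: list):
    """Every set partition of a small list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity(graph, partition: list[list]) -> float:
    import networkx as nx

    return nx.community.modularity(graph, [set(p) for p in partition], weight="weight")
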
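"""Completeness calling, candidate-MGE selection, and ANI dereplication.

A contig is called complete when it carries an end-anchored terminal repeat:
its first L bases equal its last L bases (direct terminal repeat, DTR) or
the reverse complement of them (inverted, ITR), for some L >= 20 with at
most 10% mismatches.  Candidates are then selected by the discovery rule:
contigs >= 2 kbp with >= 2 protospacer matches at >= 90% identity, or >= 1
match when completeness can be predicted.  Finally candidates are
dereplicated by greedy clustering at >= 98% ANI and >= 95% coverage of the
shorter sequence, with the longest member as representative.

ANI is computed by anchor chaining: maximal exact matches (>= 15 nt) are
greedily chained co-linearly, inter-anchor gaps up to 500 nt are closed by
global alignment, and ANI is matched/aligned columns over the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .protospacers import ProtospacerHit
from .seqs import encode, kmer_codes, revcomp

logger = logging.getLogger(__name__)


@dataclass
class CompletenessCall:
    contig_id: str
    kind: str  # "DTR" | "ITR" | "none"
    repeat_length: int = 0
    mismatches: int = 0
    mismatch_fraction: float = 0.0
    reason: str = ""

    @property
    def is_complete(self) -> bool:
        return self.kind != "none"


@dataclass
class CandidateMGE:
    contig_id: str
    length: int
    hits: list[ProtospacerHit]
    n_hits: int
    completeness: CompletenessCall
    selection_branch: str  # "multi_hit" | "single_hit_complete"
    host_flagged: bool = False


@dataclass
class DedupCluster:
    representative: str
    members: list[tuple[str, float, float]]  # (contig_id, ani, coverage_short)


# --------------------------------------------------------------------------
# terminal repeats
# --------------------------------------------------------------------------


def _end_repeat_mismatches(enc: np.ndarray, L: int, kind: str) -> int:
    """Mismatches of the end-anchored repeat of length L (DTR or ITR)."""
    a = enc[:L]
    b = enc[len(enc) - L :]
    if kind == "ITR":
        b = b[::-1].copy()
        acgt = b < 4
        b[acgt] = 3 - b[acgt]
    return int(np.count_nonzero((a != b) | (a > 3) | (b > 3)))


def find_terminal_repeats(
    contig: str,
    contig_id: str = "",
    min_len: int = 20,
    max_mismatch_frac: float = 0.10,
    window: int = 2000,
    seed_k: int = 6,
) -> CompletenessCall:
    """Call DTR/ITR completeness by comparing the contig's two ends.

    Only end-anchored repeats count (they must include position 0 and the
    final position).  DTR candidates are seeded by exact k-mers shared
    between the first and last ``window`` bases at a consistent end-anchored
    offset; k=6 is pigeonhole-safe for every admissible repeat (a 20 bp
    repeat with 2 mismatches still contains an exact 6-mer).  ITR candidates
    need no seeding: the anti-diagonal alignment is position-independent, so
    a single cumulative scan is exact.  The longest qualifying repeat is
    reported, DTR preferred over ITR on length ties.
    """
    n = len(contig)
    if n < 2 * min_len:
        return CompletenessCall(contig_id, "none", reason="contig shorter than 2*min_len")
    enc = encode(contig)
    limit = min(window, n // 2)

    # DTR: shared k-mer at prefix position p / global suffix position g
    # implies candidate repeat length L = p + (n - g).
    prefix_codes = kmer_codes(enc[:limit], seed_k)
    suffix_codes = kmer_codes(enc[n - limit :], seed_k)
    lut: dict[int, list[int]] = {}
    for p, c in enumerate(prefix_codes):
        if c >= 0:
            lut.setdefault(int(c), []).append(p)
    dtr_lengths: set[int] = set()
    for q, c in enumerate(suffix_codes):
        if c < 0 or int(c) not in lut:
            continue
        g = n - limit + q
        for p in lut[int(c)]:
            L = p + (n - g)
            if min_len <= L <= limit:
                dtr_lengths.add(L)

    best: CompletenessCall | None = None
    for L in sorted(dtr_lengths, reverse=True):
        mm = _end_repeat_mismatches(enc, L, "DTR")
        if mm <= max_mismatch_frac * L + 1e-9:
            best = CompletenessCall(contig_id, "DTR", L, mm, mm / L)
            break

    # ITR: mismatch profile along the fixed anti-diagonal
    a = enc[:limit]
    b = enc[n - limit :][::-1].copy()
    acgt = b < 4
    b[acgt] = 3 - b[acgt]
    mism = ((a != b) | (a > 3) | (b > 3)).astype(np.int64)
    cum = np.cumsum(mism)
    for L in range(limit, min_len - 1, -1):
        if best is not None and L <= best.repeat_length:
            break  # DTR preferred on ties
        mm = int(cum[L - 1])
        if mm <= max_mismatch_frac * L + 1e-9:
            best = CompletenessCall(contig_id, "ITR", L, mm, mm / L)
            break

    return best if best is not None else CompletenessCall(contig_id, "none")


# --------------------------------------------------------------------------
# candidate selection
# --------------------------------------------------------------------------


def select_candidates(
    contigs: dict[str, str],
    hits: list[ProtospacerHit],
    completeness_calls: dict[str, CompletenessCall],
    min_len: int = 2000,
    min_hits: int = 2,
    min_identity: float = 0.90,
) -> list[CandidateMGE]:
    """Apply the two-branch candidate-MGE selection rule.

    Branch ``multi_hit``: length >= min_len and >= min_hits distinct
    (spacer, position) matches at >= min_identity.  Branch
    ``single_hit_complete``: length >= min_len, >= 1 match, and a terminal
    repeat predicts completeness.  The length floor applies to both
    branches.  Hits are expected to be identity-filtered and array-masked
    already; the identity threshold is re-applied defensively.
    """
    by_contig: dict[str, list[ProtospacerHit]] = {}
    for h in hits:
        if h.identity >= min_identity - 1e-12:
            by_contig.setdefault(h.contig_id, []).append(h)
    out: list[CandidateMGE] = []
    for cid in contigs:
        chits = by_contig.get(cid, [])
        n_hits = len({(h.spacer_id, h.start) for h in chits})
        if n_hits == 0 or len(contigs[cid]) < min_len:
            continue
        comp = completeness_calls.get(cid, CompletenessCall(cid, "none"))
        if n_hits >= min_hits:
            branch = "multi_hit"
        elif comp.is_complete:
            branch = "single_hit_complete"
        else:
            continue
        out.append(
            CandidateMGE(cid, len(contigs[cid]), chits, n_hits, comp, branch)
        )
    return out


# --------------------------------------------------------------------------
# ANI by anchor chaining
# --------------------------------------------------------------------------


@dataclass
class _Anchor:
    pa: int
    pb: int
    length: int


def _maximal_exact_matches(ea: np.ndarray, eb: np.ndarray, k: int) -> list[_Anchor]:
    """Maximal exact matches >= k via shared k-mers merged along diagonals."""
    ca = kmer_codes(ea, k)
    cb = kmer_codes(eb, k)
    vb = np.flatnonzero(cb >= 0)
    if len(vb) == 0:
        return []
    order = vb[np.argsort(cb[vb], kind="stable")]
    sorted_cb = cb[order]
    va = np.flatnonzero(ca >= 0)
    lo = np.searchsorted(sorted_cb, ca[va], side="left")
    hi = np.searchsorted(sorted_cb, ca[va], side="right")
    pairs_a: list[np.ndarray] = []
    pairs_b: list[np.ndarray] = []
    for i, (a_pos, l, h) in enumerate(zip(va, lo, hi)):
        if h > l:
            pairs_b.append(order[l:h])
            pairs_a.append(np.full(h - l, a_pos, dtype=np.int64))
    if not pairs_a:
        return []
    pa = np.concatenate(pairs_a)
    pb = np.concatenate(pairs_b)
    diag = pa - pb
    # sort by (diagonal, position) then merge consecutive k-mer starts
    order2 = np.lexsort((pa, diag))
    pa, pb, diag = pa[order2], pb[order2], diag[order2]
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(pa) != 1)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(pa)]))
    return [
        _Anchor(int(pa[s]), int(pb[s]), int(pa[e - 1] - pa[s]) + k)
        for s, e in zip(starts, ends)
    ]


def _align_gap(a: str, b: str) -> tuple[int, int]:
    """(matched columns, total columns) of a global alignment of two gaps."""
    if not a and not b:
        return 0, 0
    if not a or not b:
        return 0, max(len(a), len(b))
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
    return matched, cols


def _chain_and_score(
    sa: str, sb: str, min_anchor: int, max_gap: int
) -> tuple[int, int, int, int]:
    """Chain anchors co-linearly; returns (matched, columns, a_res, b_res)."""
    ea, eb = encode(sa), encode(sb)
    anchors = [x for x in _maximal_exact_matches(ea, eb, 15) if x.length >= min_anchor]
    # greedy by descending length; symmetric tie-breaks
    anchors.sort(key=lambda x: (-x.length, x.pa + x.pb, min(x.pa, x.pb)))
    chain: list[_Anchor] = []
    for anc in anchors:
        ins = 0
        while ins < len(chain) and chain[ins].pa < anc.pa:
            ins += 1
        prev = chain[ins - 1] if ins > 0 else None
        nxt = chain[ins] if ins < len(chain) else None
        if prev and (anc.pa < prev.pa + prev.length or anc.pb < prev.pb + prev.length):
            continue
        if nxt and (anc.pa + anc.length > nxt.pa or anc.pb + anc.length > nxt.pb):
            continue
        chain.insert(ins, anc)
    if not chain:
        return 0, 0, 0, 0
    matched = cols = a_res = b_res = 0
    for i, anc in enumerate(chain):
        if i > 0:
            prev = chain[i - 1]
            ga = sa[prev.pa + prev.length : anc.pa]
            gb = sb[prev.pb + prev.length : anc.pb]
            if max(len(ga), len(gb)) <= max_gap:
                gm, gc = _align_gap(ga, gb)
                matched += gm
                cols += gc
                a_res += len(ga)
                b_res += len(gb)
        matched += anc.length
        cols += anc.length
        a_res += anc.length
        b_res += anc.length
    return matched, cols, a_res, b_res


def pairwise_ani(
    a: str, b: str, min_anchor: int = 15, max_gap: int = 500
) -> tuple[float, float, str]:
    """ANI and shorter-sequence coverage of two contigs.

    Both orientations of the second sequence are evaluated and the one with
    more matched columns wins (ties to forward).  Returns
    ``(ani, coverage_short, orientation)``; ``(0.0, 0.0, "+")`` when no
    anchor chain exists.  Symmetric by construction: the pair is canonically
    ordered internally, so ``pairwise_ani(a, b) == pairwise_ani(b, a)``.
    """
    # canonical internal order makes the result exactly symmetric
    sa, sb = sorted((a, b), key=lambda s: (len(s), s))
    short_len = len(sa)
    best = (0, 0, 0, 0)
    best_orient = "+"
    for orient, sb_or in (("+", sb), ("-", revcomp(sb))):
        score = _chain_and_score(sa, sb_or, min_anchor, max_gap)
        if score[0] > best[0]:
            best = score
            best_orient = orient
    matched, cols, a_res, _b_res = best
    if cols == 0:
        return 0.0, 0.0, "+"
    return matched / cols, a_res / short_len, best_orient


# --------------------------------------------------------------------------
# dereplication
# --------------------------------------------------------------------------


def dedup_candidates(
    sequences: dict[str, str],
    min_ani: float = 0.98,
    min_cov: float = 0.95,
    min_anchor: int = 15,
    max_gap: int = 500,
) -> list[DedupCluster]:
    """Greedy dereplication at >= min_ani ANI and >= min_cov coverage.

    Contigs are visited by descending length (ties lexicographic by id);
    each joins the first existing cluster whose representative satisfies
    both thresholds, else founds a cluster.  Deterministic.
    """
    order = sorted(sequences, key=lambda cid: (-len(sequences[cid]), cid))
    clusters: list[DedupCluster] = []
    for cid in order:
        placed = False
        for cl in clusters:
            ani, cov, _orient = pairwise_ani(
                sequences[cl.representative], sequences[cid], min_anchor, max_gap
            )
            if ani >= min_ani - 1e-12 and cov >= min_cov - 1e-12:
                cl.members.append((cid, ani, cov))
                placed = True
                break
        if not placed:
            clusters.append(DedupCluster(cid, [(cid, 1.0, 1.0)]))
    return clusters


def screen_against_hosts(
    candidates: list[CandidateMGE],
    sequences: dict[str, str],
    host_genomes: dict[str, str],
    min_ani: float = 0.98,
    min_cov: float = 0.50,
) -> list[CandidateMGE]:
    """Flag candidates that look like host genome fragments (in place).

    A candidate whose best ANI/coverage against any supplied host genome
    reaches both thresholds is flagged, not dropped: the flag replaces the
    manual curation step with an explicit, auditable rule.
    """
    for cand in candidates:
        for hseq in host_genomes.values():
            ani, cov, _ = pairwise_ani(sequences[cand.contig_id], hseq)
            if ani >= min_ani - 1e-12 and cov >= min_cov - 1e-12:
                cand.host_flagged = True
                break
    return candidates
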
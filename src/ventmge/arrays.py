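"""Detection of CRISPR repeat-spacer arrays and spacer catalog extraction.

Arrays are found de novo by an exact k-mer seed-and-extend scan: a k-mer
(default k=8) recurring at admissible spacing (repeat+spacer period) starts a
candidate; the repeat window is grown across all instances while every
instance stays within a mismatch budget of the per-column majority consensus,
then trimmed back to unanimous end columns.  Candidates are kept only if the
repeat length falls in the configured window (29-31 nt for Thermococcales),
spacer lengths are plausible, and at least ``min_repeats`` copies are
present.  Overlapping candidates are resolved by most repeat instances, then
longest span, then leftmost start.

Detected repeats are anchored to a reference repeat set at <=1 mismatch on
either strand (equal lengths only — Hamming distance), which restricts the
metagenomic spacer catalog to arrays of the host lineage of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqs import encode, hamming, kmer_codes, revcomp

logger = logging.getLogger(__name__)


@dataclass
class DetectParams:
    """Tunable knobs of the array detector.

    Only the repeat-length window is dictated by the host lineage (all
    Thermococcales repeats are 29-31 nt); the remaining defaults mirror
    common CRT/MinCED-style behaviour.
    """

    min_repeat_len: int = 29
    max_repeat_len: int = 31
    min_spacer_len: int = 20
    max_spacer_len: int = 60
    min_repeats: int = 3
    max_divergence: int = 2  # mismatches allowed per instance vs consensus
    seed_k: int = 8
    max_paths_per_seed: int = 2000

    @property
    def min_gap(self) -> int:
        return self.min_repeat_len + self.min_spacer_len

    @property
    def max_gap(self) -> int:
        return self.max_repeat_len + self.max_spacer_len


@dataclass
class CrisprArray:
    """One detected repeat-spacer locus (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_instances: list[tuple[int, str]]
    spacers: list[tuple[int, int, str]]
    anchored: bool = False
    anchor_repeat_id: str | None = None
    anchor_orientation: str | None = None
    anchor_distance: int | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_instances)


@dataclass
class Spacer:
    """A unique spacer sequence with provenance."""

    spacer_id: str
    sequence: str
    length: int
    sources: list[tuple[str, str, int]]  # (contig_id, array locus, ordinal)
    origin_class: str  # "isolate_genome" | "metagenome"


@dataclass
class AnchorMatch:
    repeat_id: str
    orientation: str  # "+" (forward) | "-" (reverse complement)
    distance: int


# --------------------------------------------------------------------------
# candidate growth: shared semantics of detector and test oracle
# --------------------------------------------------------------------------


def _column(enc: np.ndarray, anchors: np.ndarray, off: int):
    """Consensus/mismatch info for one window column, or None if out of range.

    Consensus is the majority ACGT base, ties broken alphabetically;
    non-ACGT bases never join the consensus and always count as mismatches.
    """
    idx = anchors + off
    if idx[0] < 0 or idx[-1] >= len(enc):
        return None
    bases = enc[idx]
    acgt = bases < 4
    if not acgt.any():
        return None
    counts = np.bincount(bases[acgt], minlength=4)
    cons = int(np.flatnonzero(counts == counts.max())[0])
    mism = (bases != cons) | ~acgt
    return mism, bool(not mism.any()), acgt


def grow_candidate(
    enc: np.ndarray, anchors: list[int], seed_len: int, params: DetectParams
) -> tuple[int, int, np.ndarray] | None:
    """Grow a repeat window from exact-seed anchors; returns (l, r, costs).

    ``l``/``r`` are offsets relative to the anchor positions (seed occupies
    [0, seed_len)).  Extension proceeds right then left while every
    instance's total mismatch count against the per-column consensus stays
    within ``max_divergence`` and the window stays below a hard cap; runs of
    more than two non-ACGT columns in an instance stop extension.  End
    columns are then trimmed until the terminal column is unanimous, which
    pins boundaries that the mismatch budget alone would over-run.
    """
    P = np.asarray(anchors, dtype=np.int64)
    m = len(P)
    cap = params.max_repeat_len + 2 * params.max_divergence
    cost = np.zeros(m, dtype=np.int64)
    cols: dict[int, tuple[np.ndarray, bool]] = {
        off: (np.zeros(m, dtype=bool), True) for off in range(seed_len)
    }
    l, r = 0, seed_len

    for direction in (+1, -1):
        nrun = np.zeros(m, dtype=np.int64)
        while r - l < cap:
            off = r if direction == +1 else l - 1
            info = _column(enc, P, off)
            if info is None:
                break
            mism, unan, acgt = info
            nxt = np.where(~acgt, nrun + 1, 0)
            if (nxt > 2).any():
                break
            if ((cost + mism) > params.max_divergence).any():
                break
            cost += mism
            cols[off] = (mism, unan)
            nrun = nxt
            if direction == +1:
                r += 1
            else:
                l -= 1

    while r > l and not cols[r - 1][1]:
        cost -= cols[r - 1][0]
        r -= 1
    while r > l and not cols[l][1]:
        cost -= cols[l][0]
        l += 1
    if r <= l:
        return None
    return int(l), int(r), cost


def validate_candidate(
    anchors: list[int], l: int, r: int, cost: np.ndarray, params: DetectParams
) -> bool:
    """Repeat-length / spacer-length / copy-number admissibility check."""
    rep_len = r - l
    if not params.min_repeat_len <= rep_len <= params.max_repeat_len:
        return False
    if len(anchors) < params.min_repeats:
        return False
    if (cost > params.max_divergence).any():
        return False
    for a, b in zip(anchors, anchors[1:]):
        spacer_len = (b + l) - (a + r)
        if not params.min_spacer_len <= spacer_len <= params.max_spacer_len:
            return False
    return True


def resolve_overlaps(
    candidates: list[tuple[tuple[int, ...], int, int]]
) -> list[tuple[tuple[int, ...], int, int]]:
    """Greedy selection of non-overlapping candidates.

    Candidates are ``(instance_starts, repeat_len, span_end)`` with span
    ``[starts[0], span_end)``; priority is most instances, then longest
    span, then leftmost start.
    """
    uniq = sorted(set(candidates), key=lambda c: (-len(c[0]), -(c[2] - c[0][0]), c[0][0], c[0]))
    accepted: list[tuple[tuple[int, ...], int, int]] = []
    spans: list[tuple[int, int]] = []
    for cand in uniq:
        s, e = cand[0][0], cand[2]
        if all(e <= s0 or s >= e0 for s0, e0 in spans):
            accepted.append(cand)
            spans.append((s, e))
    return sorted(accepted, key=lambda c: c[0][0])


def _maximal_paths(positions: np.ndarray, params: DetectParams) -> list[list[int]]:
    """All maximal chains of positions with consecutive gaps in the period window."""
    pos = positions
    n = len(pos)
    succs: list[np.ndarray] = []
    has_pred = np.zeros(n, dtype=bool)
    for i in range(n):
        jlo = int(np.searchsorted(pos, pos[i] + params.min_gap, side="left"))
        jhi = int(np.searchsorted(pos, pos[i] + params.max_gap, side="right"))
        s = np.arange(jlo, jhi)
        succs.append(s)
        has_pred[s] = True
    paths: list[list[int]] = []
    stack: list[list[int]] = [[i] for i in range(n) if not has_pred[i]]
    while stack:
        path = stack.pop()
        nxt = succs[path[-1]]
        if len(nxt) == 0:
            if len(path) >= params.min_repeats:
                paths.append([int(pos[i]) for i in path])
        else:
            for j in nxt:
                if len(paths) + len(stack) > params.max_paths_per_seed:
                    break
                stack.append(path + [int(j)])
    return paths


def detect_arrays(
    sequence: str, params: DetectParams | None = None, contig_id: str = ""
) -> list[CrisprArray]:
    """Detect maximal non-overlapping CRISPR arrays in one sequence."""
    params = params or DetectParams()
    enc = encode(sequence)
    n = len(enc)
    if n < 2 * params.min_repeat_len:
        return []

    codes = kmer_codes(enc, params.seed_k)
    valid = np.flatnonzero(codes >= 0)
    if len(valid) == 0:
        return []
    order = valid[np.argsort(codes[valid], kind="stable")]
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(order)]))

    candidates: list[tuple[tuple[int, ...], int, int]] = []
    growths: dict[tuple[tuple[int, ...], int], tuple[int, int]] = {}
    for a, b in zip(starts, ends):
        if b - a < params.min_repeats:
            continue
        positions = np.sort(order[a:b])
        gaps = np.diff(positions)
        # quick reject: no admissible consecutive gap at all
        if not ((gaps >= params.min_gap) & (gaps <= params.max_gap)).any():
            continue
        # a seed k-mer recurring closer than the minimum array period is a
        # tandem/micro-repeat, not a CRISPR period; such ambiguous seed
        # groups are skipped (a genuine array is still found through its
        # other, unambiguous seed offsets)
        if (gaps < params.min_gap).any():
            continue
        for anchors in _maximal_paths(positions, params):
            grown = grow_candidate(enc, anchors, params.seed_k, params)
            if grown is None:
                continue
            l, r, cost = grown
            if not validate_candidate(anchors, l, r, cost, params):
                continue
            inst = tuple(p + l for p in anchors)
            rep_len = r - l
            candidates.append((inst, rep_len, inst[-1] + rep_len))
            growths[(inst, rep_len)] = (l, r)

    out: list[CrisprArray] = []
    for inst, rep_len, span_end in resolve_overlaps(candidates):
        instances = [(s, sequence[s : s + rep_len]) for s in inst]
        spacers = [
            (a + rep_len, b, sequence[a + rep_len : b])
            for a, b in zip(inst, inst[1:])
        ]
        arr = CrisprArray(
            contig_id=contig_id,
            start=inst[0],
            end=span_end,
            repeat_consensus="",
            repeat_instances=instances,
            spacers=spacers,
        )
        arr.repeat_consensus = consensus_repeat(arr)
        out.append(arr)
    return out


def consensus_repeat(array: CrisprArray) -> str:
    """Per-column majority consensus of the repeat instances.

    Ties break to the alphabetically first base; consensus length is the
    modal instance length (ties to the shorter).  Columns with no ACGT base
    yield N.
    """
    seqs = [s for _p, s in array.repeat_instances]
    if not seqs:
        raise ValueError("array has no repeat instances")
    lengths = sorted({len(s) for s in seqs})
    modal = max(lengths, key=lambda L: (sum(1 for s in seqs if len(s) == L), -L))
    cols = []
    for j in range(modal):
        counts: dict[str, int] = {}
        for s in seqs:
            if j < len(s) and s[j] in "ACGT":
                counts[s[j]] = counts.get(s[j], 0) + 1
        if not counts:
            cols.append("N")
        else:
            best = max(counts.values())
            cols.append(sorted(b for b, c in counts.items() if c == best)[0])
    return "".join(cols)


def match_repeat_to_reference(
    repeat: str,
    references: list[tuple[str, str]] | dict[str, str],
    max_mismatches: int = 1,
) -> AnchorMatch | None:
    """Anchor a repeat to a reference set at <=1 mismatch, either strand.

    Hamming distance over equal lengths only; references of any other
    length never match.  Among multiple matches the minimum distance wins,
    ties by reference order (forward orientation before reverse).
    """
    refs = list(references.items()) if isinstance(references, dict) else list(references)
    rc = revcomp(repeat)
    best: tuple[int, int, int] | None = None
    best_match: AnchorMatch | None = None
    for idx, (rid, ref) in enumerate(refs):
        if len(ref) != len(repeat):
            continue
        for orient_rank, (query, orient) in enumerate(((repeat, "+"), (rc, "-"))):
            d = hamming(query, ref)
            if d <= max_mismatches:
                key = (d, idx, orient_rank)
                if best is None or key < best:
                    best = key
                    best_match = AnchorMatch(rid, orient, d)
    return best_match


def anchor_arrays(
    arrays: list[CrisprArray],
    references: list[tuple[str, str]] | dict[str, str],
    max_mismatches: int = 1,
) -> list[CrisprArray]:
    """Annotate each array with its reference-repeat anchor (in place)."""
    for arr in arrays:
        m = match_repeat_to_reference(arr.repeat_consensus, references, max_mismatches)
        if m is not None:
            arr.anchored = True
            arr.anchor_repeat_id = m.repeat_id
            arr.anchor_orientation = m.orientation
            arr.anchor_distance = m.distance
    return arrays


def extract_spacers(
    arrays: list[CrisprArray], origin_class: str = "metagenome"
) -> list[Spacer]:
    """Extract spacers in array order with provenance.

    Unanchored metagenomic arrays contribute nothing (the anchor filter is
    what restricts the catalog to the host lineage); isolate-genome arrays
    are kept regardless.  Spacers containing non-ACGT characters are dropped
    with a logged count.
    """
    if origin_class not in ("isolate_genome", "metagenome"):
        raise ValueError(f"unknown origin_class: {origin_class}")
    out: list[Spacer] = []
    n_dropped = 0
    for arr in arrays:
        if origin_class == "metagenome" and not arr.anchored:
            continue
        locus = f"{arr.contig_id}:{arr.start}-{arr.end}"
        for ordinal, (_s, _e, seq) in enumerate(arr.spacers):
            if any(b not in "ACGT" for b in seq):
                n_dropped += 1
                continue
            out.append(
                Spacer(
                    spacer_id="",
                    sequence=seq,
                    length=len(seq),
                    sources=[(arr.contig_id, locus, ordinal)],
                    origin_class=origin_class,
                )
            )
    if n_dropped:
        logger.info("dropped %d spacers containing non-ACGT characters", n_dropped)
    return out


def dedup_spacers(spacers: list[Spacer]) -> list[Spacer]:
    """Exact-sequence deduplication into a unique spacer catalog.

    Orientation-sensitive (a spacer and its reverse complement are distinct
    catalog entries); provenance lists are merged and ids assigned by first
    occurrence.  A spacer seen in both isolate genomes and metagenomes is
    classed as isolate_genome.
    """
    catalog: dict[str, Spacer] = {}
    for sp in spacers:
        if sp.sequence in catalog:
            entry = catalog[sp.sequence]
            entry.sources.extend(sp.sources)
            if sp.origin_class == "isolate_genome":
                entry.origin_class = "isolate_genome"
        else:
            catalog[sp.sequence] = Spacer(
                spacer_id=f"sp{len(catalog):05d}",
                sequence=sp.sequence,
                length=sp.length,
                sources=list(sp.sources),
                origin_class=sp.origin_class,
            )
    return list(catalog.values())
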
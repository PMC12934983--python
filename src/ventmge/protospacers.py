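"""Spacer-to-contig protospacer search at >=90% full-length identity.

Matching is full-length and ungapped: a hit is a contig window of spacer
length whose Hamming distance to the spacer (in either orientation) is at
most ``floor((1 - min_identity) * L)``.  Candidate windows are seeded with
exact k-mers through a pigeonhole scheme — the spacer is split into m+1
disjoint blocks (m = mismatch budget), so any window within budget shares at
least one exact block — and every seeded window is verified by full-length
comparison.  This makes the seeded search provably equivalent to an
exhaustive scan over every (position, strand) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .arrays import CrisprArray, Spacer
from .seqs import encode, kmer_codes, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 7  # admissible for the shortest 30-nt spacer at 10% mismatches


@dataclass
class ProtospacerHit:
    """One spacer match on a contig (forward-strand, half-open coordinates)."""

    spacer_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    identity: float

    def sort_key(self):
        return (self.contig_id, self.start, self.spacer_id, self.strand)


def admissible_seed_k(min_spacer_len: int, min_identity: float = 0.90) -> int:
    """Largest seed length with a pigeonhole sensitivity guarantee.

    For the worst case (shortest spacer Lmin with m = floor((1-id)*Lmin)
    mismatches) the spacer splits into m+1 disjoint blocks of length
    floor(Lmin/(m+1)); any window within budget leaves one block exact.
    """
    m = int(np.floor((1.0 - min_identity) * min_spacer_len + 1e-9))
    return min_spacer_len // (m + 1)


class ContigIndex:
    """Exact k-mer -> (contig, position) postings over a contig set.

    Contigs are concatenated with k sentinel (non-ACGT) bases between them,
    so no k-mer window spans two contigs; lookups run against one sorted
    global code array.
    """

    def __init__(self, contigs: dict[str, str], k: int = DEFAULT_SEED_K):
        self.k = k
        self.contig_ids: list[str] = []
        self.offsets: list[int] = []  # global start of each contig
        self.lengths: list[int] = []
        parts: list[np.ndarray] = []
        pos = 0
        sentinel = np.full(k, 4, dtype=np.uint8)
        n_short = 0
        for cid, seq in contigs.items():
            if len(seq) < k:
                n_short += 1
                continue
            enc = encode(seq)
            self.contig_ids.append(cid)
            self.offsets.append(pos)
            self.lengths.append(len(enc))
            parts.append(enc)
            parts.append(sentinel)
            pos += len(enc) + k
        if n_short:
            logger.info("left %d contigs shorter than k=%d unindexed", n_short, k)
        self.concat = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        )
        codes = kmer_codes(self.concat, k)
        valid = np.flatnonzero(codes >= 0)
        order = valid[np.argsort(codes[valid], kind="stable")]
        self.sorted_codes = codes[order]
        self.sorted_positions = order
        self._offsets_arr = np.asarray(self.offsets, dtype=np.int64)

    def n_postings(self, kmer: str) -> int:
        """Number of occurrences of an exact k-mer across the contig set."""
        code = kmer_codes(encode(kmer), self.k)
        if len(code) == 0 or code[0] < 0:
            return 0
        lo = np.searchsorted(self.sorted_codes, code[0], side="left")
        hi = np.searchsorted(self.sorted_codes, code[0], side="right")
        return int(hi - lo)

    def lookup(self, codes: np.ndarray) -> list[np.ndarray]:
        """Global positions of each queried k-mer code."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return [self.sorted_positions[a:b] for a, b in zip(lo, hi)]

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global positions to (contig index, local position)."""
        ci = np.searchsorted(self._offsets_arr, gpos, side="right") - 1
        return ci, gpos - self._offsets_arr[ci]


def index_contigs(contigs: dict[str, str], k: int = DEFAULT_SEED_K) -> ContigIndex:
    """Build the exact k-mer position index used to seed the search."""
    return ContigIndex(contigs, k)


def search_spacers(
    spacers: list[Spacer],
    contigs: dict[str, str],
    index: ContigIndex | None = None,
    min_identity: float = 0.90,
) -> list[ProtospacerHit]:
    """Find all full-length ungapped spacer matches at >= min_identity.

    Both orientations are searched; hits are reported on forward-strand
    coordinates with strand "-" meaning the reverse complement of the spacer
    matches the contig.  Spacers shorter than the seed length are skipped
    with a log message.  Output is sorted by (contig, start, spacer).
    """
    if index is None:
        index = index_contigs(contigs)
    k = index.k
    concat = index.concat
    hits: list[ProtospacerHit] = []
    n_skipped = 0
    for sp in spacers:
        L = sp.length
        if L < k:
            n_skipped += 1
            continue
        m_max = int(np.floor((1.0 - min_identity) * L + 1e-9))
        n_blocks = m_max + 1
        # disjoint pigeonhole blocks; precondition k <= floor(L/(m+1))
        block_offsets = [(i * L) // n_blocks for i in range(n_blocks)]
        for strand, oriented in (("+", sp.sequence), ("-", revcomp(sp.sequence))):
            enc_sp = encode(oriented)
            q_codes = kmer_codes(enc_sp, k)
            block_codes = np.asarray([q_codes[off] for off in block_offsets])
            ok = block_codes >= 0
            if not ok.any():
                continue
            starts: list[np.ndarray] = []
            for off, code in zip(np.asarray(block_offsets)[ok], block_codes[ok]):
                for gpos in index.lookup(np.asarray([code])):
                    starts.append(gpos - off)
            if not starts:
                continue
            cand = np.unique(np.concatenate(starts))
            cand = cand[(cand >= 0) & (cand + L <= len(concat))]
            if len(cand) == 0:
                continue
            # verify every candidate window by full-length Hamming comparison
            win = concat[cand[:, None] + np.arange(L)[None, :]]
            bad = (win > 3) | (enc_sp > 3)[None, :]
            mm = np.count_nonzero((win != enc_sp[None, :]) | bad, axis=1)
            keep = mm <= m_max
            if not keep.any():
                continue
            ci, local = index.locate(cand[keep])
            for c, pos, d in zip(ci, local, mm[keep]):
                if pos + L > index.lengths[c]:
                    continue  # window runs into the inter-contig sentinel
                hits.append(
                    ProtospacerHit(
                        spacer_id=sp.spacer_id,
                        contig_id=index.contig_ids[c],
                        start=int(pos),
                        end=int(pos) + L,
                        strand=strand,
                        mismatches=int(d),
                        identity=(L - int(d)) / L,
                    )
                )
    if n_skipped:
        logger.info("skipped %d spacers shorter than seed length k=%d", n_skipped, k)
    hits.sort(key=ProtospacerHit.sort_key)
    return hits


def mask_array_hits(
    hits: list[ProtospacerHit], arrays: list[CrisprArray]
) -> tuple[list[ProtospacerHit], int]:
    """Drop hits overlapping any detected CRISPR array interval.

    Spacers trivially match the arrays they came from (and arrays of related
    hosts); such self-matches are not protospacer evidence.  Returns the
    retained hits and the number removed.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for arr in arrays:
        spans.setdefault(arr.contig_id, []).append((arr.start, arr.end))
    kept: list[ProtospacerHit] = []
    removed = 0
    for h in hits:
        overlapping = any(
            h.start < e and s < h.end for s, e in spans.get(h.contig_id, ())
        )
        if overlapping:
            removed += 1
        else:
            kept.append(h)
    return kept, removed
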
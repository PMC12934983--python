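"""Low-level nucleotide sequence utilities shared across the pipeline.

Sequences are handled as uppercase strings at module boundaries and as
``numpy`` ``uint8`` arrays internally (A=0, C=1, G=2, T=3; anything else,
including N, is 4 and is treated as a universal mismatch).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGTN"), dtype="U1")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (non-ACGT -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[np.minimum(arr, 4)])


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def hamming(a: str | np.ndarray, b: str | np.ndarray) -> int:
    """Hamming distance between equal-length sequences.

    Positions where either sequence is non-ACGT count as mismatches, so two
    Ns never spuriously agree.
    """
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if len(ea) != len(eb):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero((ea != eb) | (ea > 3) | (eb > 3)))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of every k-mer; windows with non-ACGT get -1.

    Returns an int64 array of length ``len(arr) - k + 1`` (empty if the
    sequence is shorter than k).
    """
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    bad = np.zeros(n - k + 1, dtype=bool)
    a64 = arr.astype(np.int64)
    for t in range(k):
        col = a64[t : n - k + 1 + t]
        codes = codes * 4 + np.minimum(col, 3)
        bad |= col > 3
    codes[bad] = -1
    return codes


def sliding_mismatches(contig: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``contig``.

    Exhaustive sliding-window comparison; returns an array of length
    ``len(contig) - len(query) + 1``.
    """
    n, L = len(contig), len(query)
    if n < L:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(contig, L)
    bad = (win > 3) | (query > 3)
    return np.count_nonzero((win != query) | bad, axis=1).astype(np.int64)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]] | dict[str, str]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))
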
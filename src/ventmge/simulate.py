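"""Seeded synthetic vent-metagenome generator with a ground-truth manifest.

Emulates the inputs the discovery pipeline assumes: archaeal host genomes
carrying CRISPR arrays (29-31 nt repeats, spacers with median ~37 nt), a pool
of mobile genetic elements (MGEs) organised into families that share diverged
protein-coding core modules, protospacers planted at controlled nucleotide
identity, complete genomes marked by direct or inverted terminal repeats, and
unrelated decoy contigs.  Every planted feature is recorded in a
:class:`TruthManifest` so each pipeline stage can be scored against the truth
by independent brute-force re-checks.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SimParams.seed``; identical parameters produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqs import random_dna, revcomp, write_fasta

# sense codons of translation table 11, grouped by amino acid
_CODON_TABLE: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_AMINO_ACIDS = sorted(_CODON_TABLE)
_START_CODONS = ["ATG", "GTG", "TTG"]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its constraints."""


@dataclass
class SimParams:
    """Scenario parameters for the synthetic vent metagenome.

    Defaults describe the standard test scenario: 5 MGE families of 4 members
    targeted by the CRISPR arrays of 3 host genomes, embedded among ~450
    decoy contigs (~500 contigs overall).
    """

    seed: int = 42
    n_hosts: int = 3
    n_mge_families: int = 5
    mges_per_family: int = 4
    n_reference_repeats: int = 6
    # CRISPR array structure
    repeat_length_range: tuple[int, int] = (29, 31)
    arrays_per_host: int = 2
    repeats_per_array: tuple[int, int] = (12, 25)
    repeat_variant_prob: float = 0.3
    spacer_length_range: tuple[int, int] = (30, 50)
    spacer_length_mean: float = 37.0
    spacer_length_sd: float = 4.5
    frac_mge_spacers: float = 0.7
    protospacer_identity_range: tuple[float, float] = (0.90, 1.0)
    # MGE structure
    n_core_modules: int = 10
    accessory_modules_range: tuple[int, int] = (2, 4)
    core_identity_range: tuple[float, float] = (0.45, 0.90)
    gene_length_range_aa: tuple[int, int] = (90, 200)
    intergenic_range: tuple[int, int] = (50, 150)
    frac_complete_mges: float = 0.5
    terminal_repeat_length_range: tuple[int, int] = (20, 60)
    # metagenome structure
    host_genome_length: int = 40_000
    contig_fragmentation: int = 6_000
    min_fragment_length: int = 2_500
    n_decoys: int = 450
    decoy_length_range: tuple[int, int] = (2_000, 8_000)
    gc_content: float = 0.45

    def validate(self) -> None:
        for name in (
            "repeat_variant_prob",
            "frac_mge_spacers",
            "frac_complete_mges",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.protospacer_identity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("protospacer_identity_range must satisfy 0 <= lo <= hi <= 1")
        rlo, rhi = self.repeat_length_range
        if rlo > rhi or rlo < 20:
            raise ValueError("invalid repeat_length_range")
        if self.terminal_repeat_length_range[0] < 1:
            raise ValueError("terminal repeats must be at least 1 nt")
        for name in ("n_hosts", "n_mge_families", "mges_per_family", "n_reference_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")

    # flat key=value config round-trip -------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimParams":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv.pop(f.name)
            default = getattr(cls, f.name)
            if isinstance(default, tuple):
                parts = [p for p in raw.split(",") if p]
                cast = float if any(isinstance(x, float) for x in default) else int
                kwargs[f.name] = tuple(cast(p) for p in parts)
            elif isinstance(default, bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = int(raw)
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)


# --------------------------------------------------------------------------
# truth-manifest record types
# --------------------------------------------------------------------------


@dataclass
class MgeGene:
    start: int
    end: int  # half-open, includes the stop codon
    strand: str
    module_id: str
    kind: str  # "core" | "accessory"


@dataclass
class MgeRecord:
    mge_id: str
    family_id: str
    length: int
    completeness: str  # "DTR" | "ITR" | "linear-fragment"
    tr_length: int
    genes: list[MgeGene]


@dataclass
class ProtospacerRecord:
    spacer_id: str
    mge_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class SpacerTruth:
    spacer_id: str
    sequence: str
    host_id: str
    array_index: int
    ordinal: int
    start: int  # coordinates in the host genome
    end: int
    target_mge: str | None  # None for "dark" spacers


@dataclass
class HostArrayRecord:
    host_id: str
    array_index: int
    start: int
    end: int
    repeat_id: str
    repeat_seq: str
    repeat_starts: list[int]
    spacer_ids: list[str]


@dataclass
class ContigRecord:
    contig_id: str
    origin: str  # "host" | "mge" | "decoy"
    source_id: str
    source_start: int
    source_end: int


@dataclass
class TruthManifest:
    """Machine-readable ground truth for one simulated scenario."""

    params: SimParams
    mges: list[MgeRecord] = field(default_factory=list)
    protospacers: list[ProtospacerRecord] = field(default_factory=list)
    spacers: list[SpacerTruth] = field(default_factory=list)
    host_arrays: list[HostArrayRecord] = field(default_factory=list)
    contigs: list[ContigRecord] = field(default_factory=list)

    # ---- convenience views -------------------------------------------------
    def mge_by_id(self) -> dict[str, MgeRecord]:
        return {m.mge_id: m for m in self.mges}

    def contig_origin(self) -> dict[str, str]:
        return {c.contig_id: c.origin for c in self.contigs}

    def contig_family(self) -> dict[str, str]:
        """Family label of every MGE-derived contig."""
        fam = {m.mge_id: m.family_id for m in self.mges}
        return {
            c.contig_id: fam[c.source_id]
            for c in self.contigs
            if c.origin == "mge"
        }

    def expected_contig_hits(self) -> dict[str, list[tuple[str, int, str, int]]]:
        """Planted protospacer hits per emitted contig.

        Returns ``{contig_id: [(spacer_id, start, strand, mismatches), ...]}``
        for every planted protospacer whose span falls entirely inside a
        contig cut from its source MGE.  Derived purely from manifest
        coordinates; used as the recall oracle for the search stage.
        """
        by_mge: dict[str, list[ProtospacerRecord]] = {}
        for p in self.protospacers:
            by_mge.setdefault(p.mge_id, []).append(p)
        out: dict[str, list[tuple[str, int, str, int]]] = {}
        for c in self.contigs:
            if c.origin != "mge":
                continue
            hits = []
            for p in by_mge.get(c.source_id, []):
                if p.start >= c.source_start and p.end <= c.source_end:
                    hits.append(
                        (p.spacer_id, p.start - c.source_start, p.strand, p.mismatches)
                    )
            if hits:
                out[c.contig_id] = sorted(hits, key=lambda h: (h[1], h[0]))
        return out

    # ---- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._as_dict(), indent=1, sort_keys=True) + "\n")

    def _as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        params = d["params"]
        for k, v in params.items():
            if isinstance(v, list):
                params[k] = tuple(v)
        m = cls(params=SimParams(**params))
        m.mges = [
            MgeRecord(**{**r, "genes": [MgeGene(**g) for g in r["genes"]]})
            for r in d["mges"]
        ]
        m.protospacers = [ProtospacerRecord(**r) for r in d["protospacers"]]
        m.spacers = [SpacerTruth(**r) for r in d["spacers"]]
        m.host_arrays = [HostArrayRecord(**r) for r in d["host_arrays"]]
        m.contigs = [ContigRecord(**r) for r in d["contigs"]]
        return m

    def to_tsv(self, path: str | Path) -> None:
        """TSV mirror: one commented section per record type."""
        lines: list[str] = []

        def section(name: str, header: list[str], rows: list[list]) -> None:
            lines.append(f"## {name}")
            lines.append("\t".join(header))
            for row in rows:
                lines.append("\t".join(str(x) for x in row))

        section(
            "mges",
            ["mge_id", "family_id", "length", "completeness", "tr_length", "n_genes"],
            [
                [m.mge_id, m.family_id, m.length, m.completeness, m.tr_length, len(m.genes)]
                for m in self.mges
            ],
        )
        section(
            "genes",
            ["mge_id", "start", "end", "strand", "module_id", "kind"],
            [
                [m.mge_id, g.start, g.end, g.strand, g.module_id, g.kind]
                for m in self.mges
                for g in m.genes
            ],
        )
        section(
            "protospacers",
            ["spacer_id", "mge_id", "start", "end", "strand", "mismatches"],
            [
                [p.spacer_id, p.mge_id, p.start, p.end, p.strand, p.mismatches]
                for p in self.protospacers
            ],
        )
        section(
            "spacers",
            ["spacer_id", "host_id", "array_index", "ordinal", "start", "end", "target_mge", "sequence"],
            [
                [s.spacer_id, s.host_id, s.array_index, s.ordinal, s.start, s.end,
                 s.target_mge or ".", s.sequence]
                for s in self.spacers
            ],
        )
        section(
            "host_arrays",
            ["host_id", "array_index", "start", "end", "repeat_id", "repeat_seq",
             "repeat_starts", "spacer_ids"],
            [
                [a.host_id, a.array_index, a.start, a.end, a.repeat_id, a.repeat_seq,
                 ",".join(map(str, a.repeat_starts)), ",".join(a.spacer_ids)]
                for a in self.host_arrays
            ],
        )
        section(
            "contigs",
            ["contig_id", "origin", "source_id", "source_start", "source_end"],
            [
                [c.contig_id, c.origin, c.source_id, c.source_start, c.source_end]
                for c in self.contigs
            ],
        )
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def _hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_repeat_family(
    params: SimParams, rng: np.random.Generator, n: int | None = None
) -> list[tuple[str, str]]:
    """Draw a reference set of distinct CRISPR repeat sequences.

    Repeats are 29-31 nt (``repeat_length_range``) and every equal-length
    pair is at Hamming distance >= 3, so the downstream <=1-mismatch anchor
    filter is unambiguous.
    """
    n = params.n_reference_repeats if n is None else n
    lo, hi = params.repeat_length_range
    repeats: list[tuple[str, str]] = []
    for i in range(n):
        for _attempt in range(1000):
            length = int(rng.integers(lo, hi + 1))
            seq = random_dna(rng, length, params.gc_content)
            if all(
                _hamming_str(seq, other) >= 3
                for _rid, other in repeats
                if len(other) == length
            ):
                repeats.append((f"rep{i:02d}", seq))
                break
        else:
            raise GenerationError(
                f"could not draw {n} repeats at pairwise Hamming >= 3 "
                f"within the length window {params.repeat_length_range}"
            )
    return repeats


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(len(_AMINO_ACIDS), size=length - 1)
    return "M" + "".join(_AMINO_ACIDS[i] for i in body)


def _mutate_protein(rng: np.random.Generator, protein: str, n_sub: int) -> str:
    """Substitute exactly n_sub residues (never position 0, never to the same)."""
    if n_sub == 0:
        return protein
    positions = rng.choice(len(protein) - 1, size=n_sub, replace=False) + 1
    chars = list(protein)
    for pos in positions:
        choices = [a for a in _AMINO_ACIDS if a != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _back_translate(rng: np.random.Generator, protein: str, start_codon: str, stop_codon: str) -> str:
    codons = [start_codon]
    for aa in protein[1:]:
        opts = _CODON_TABLE[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    codons.append(stop_codon)
    return "".join(codons)


def generate_mge_family(
    params: SimParams,
    rng: np.random.Generator,
    family_id: str = "fam00",
    member_ids: list[str] | None = None,
) -> tuple[dict[str, str], list[MgeRecord]]:
    """Generate one MGE family: members sharing diverged core gene modules.

    Members share ``n_core_modules`` core protein modules mutated from a
    common ancestor toward a per-module target pairwise identity drawn from
    ``core_identity_range`` (mutating exactly (1-t)/2 of sites per member
    guarantees pairwise site identity >= t), plus member-specific accessory
    ORFs.  A fraction ``frac_complete_mges`` of members carries a direct or
    inverted terminal repeat of length drawn from
    ``terminal_repeat_length_range``.
    """
    if params.mges_per_family < 1:
        raise ValueError("mges_per_family must be >= 1")
    n_members = params.mges_per_family
    if member_ids is None:
        member_ids = [f"{family_id}.m{j:02d}" for j in range(n_members)]

    aa_lo, aa_hi = params.gene_length_range_aa
    ancestors = [
        _random_protein(rng, int(rng.integers(aa_lo, aa_hi + 1)))
        for _ in range(params.n_core_modules)
    ]
    t_lo, t_hi = params.core_identity_range
    targets = rng.uniform(t_lo, t_hi, size=params.n_core_modules)

    genomes: dict[str, str] = {}
    records: list[MgeRecord] = []
    for mid in member_ids:
        genes_aa: list[tuple[str, str, str]] = []  # (module_id, kind, protein)
        for c, anc in enumerate(ancestors):
            d = (1.0 - targets[c]) / 2.0
            n_sub = int(round(d * (len(anc) - 1)))
            genes_aa.append((f"{family_id}.core{c:02d}", "core", _mutate_protein(rng, anc, n_sub)))
        n_acc = int(rng.integers(params.accessory_modules_range[0], params.accessory_modules_range[1] + 1))
        for a in range(n_acc):
            genes_aa.append(
                (f"{mid}.acc{a:02d}", "accessory",
                 _random_protein(rng, int(rng.integers(aa_lo, aa_hi + 1))))
            )

        ig_lo, ig_hi = params.intergenic_range
        parts: list[str] = [random_dna(rng, int(rng.integers(ig_lo, ig_hi + 1)), params.gc_content)]
        pos = len(parts[0])
        gene_truth: list[MgeGene] = []
        for module_id, kind, protein in genes_aa:
            start_codon = _START_CODONS[
                int(rng.choice(3, p=[0.8, 0.15, 0.05]))
            ]
            stop_codon = _STOP_CODONS[int(rng.integers(3))]
            gene_nt = _back_translate(rng, protein, start_codon, stop_codon)
            strand = "+" if rng.random() < 0.5 else "-"
            # an in-frame stop immediately upstream pins the ORF start
            cassette_fwd = "TAA" + gene_nt
            if strand == "+":
                cassette = cassette_fwd
                g_start, g_end = pos + 3, pos + 3 + len(gene_nt)
            else:
                cassette = revcomp(cassette_fwd)
                g_start, g_end = pos, pos + len(gene_nt)
            parts.append(cassette)
            pos += len(cassette)
            gene_truth.append(MgeGene(g_start, g_end, strand, module_id, kind))
            ig = random_dna(rng, int(rng.integers(ig_lo, ig_hi + 1)), params.gc_content)
            parts.append(ig)
            pos += len(ig)

        genome = "".join(parts)
        completeness, tr_length = "linear-fragment", 0
        if rng.random() < params.frac_complete_mges:
            tr_lo, tr_hi = params.terminal_repeat_length_range
            tr_length = int(rng.integers(tr_lo, tr_hi + 1))
            if rng.random() < 0.5:
                completeness = "DTR"
                genome = genome + genome[:tr_length]
            else:
                completeness = "ITR"
                genome = genome + revcomp(genome[:tr_length])
        genomes[mid] = genome
        records.append(
            MgeRecord(mid, family_id, len(genome), completeness, tr_length, gene_truth)
        )
    return genomes, records


def _sample_spacer_length(params: SimParams, rng: np.random.Generator) -> int:
    """Discretized normal around the observed median (37 nt), truncated."""
    lo, hi = params.spacer_length_range
    for _ in range(100):
        L = int(round(rng.normal(params.spacer_length_mean, params.spacer_length_sd)))
        if lo <= L <= hi:
            return L
    return int(round(params.spacer_length_mean))


def _mutate_dna(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[int(rng.integers(3))]
    return "".join(chars)


def generate_host_genome(
    params: SimParams,
    mge_pool: dict[str, str],
    rng: np.random.Generator,
    host_id: str = "host00",
    reference_repeats: list[tuple[str, str]] | None = None,
    spacer_start_index: int = 0,
) -> tuple[str, list[HostArrayRecord], list[SpacerTruth], list[ProtospacerRecord]]:
    """Generate a host genome containing CRISPR arrays that target the MGE pool.

    At least ``frac_mge_spacers`` of spacers are (possibly mutated) substrings
    of MGE genomes on either strand; the remainder are random "dark" spacers.
    Planted protospacer mismatch counts are drawn so spacer/protospacer
    identity lies exactly within ``protospacer_identity_range``.
    """
    if not mge_pool:
        raise ValueError("mge_pool must be non-empty")
    if reference_repeats is None:
        reference_repeats = generate_repeat_family(params, rng)
    mge_ids = sorted(mge_pool)
    id_lo, id_hi = params.protospacer_identity_range

    background = random_dna(rng, params.host_genome_length, params.gc_content)
    # build each array's sequence, then splice all arrays into the background
    arrays_seq: list[str] = []
    arrays_meta: list[tuple[str, str, list[int], list[dict]]] = []
    spacer_counter = spacer_start_index
    all_spacers: list[SpacerTruth] = []
    all_protos: list[ProtospacerRecord] = []

    for _ai in range(params.arrays_per_host):
        rep_id, rep_seq = reference_repeats[int(rng.integers(len(reference_repeats)))]
        n_rep = int(rng.integers(params.repeats_per_array[0], params.repeats_per_array[1] + 1))
        n_rep = max(3, n_rep)
        instances = [rep_seq] * n_rep
        if rng.random() < params.repeat_variant_prob and len(rep_seq) >= 6:
            # one interior substitution in one instance; kept away from the
            # repeat ends so array boundary trimming is unaffected
            which = int(rng.integers(n_rep))
            pos = int(rng.integers(2, len(rep_seq) - 2))
            variant = list(rep_seq)
            choices = [b for b in "ACGT" if b != variant[pos]]
            variant[pos] = choices[int(rng.integers(3))]
            instances[which] = "".join(variant)

        spacer_infos: list[dict] = []
        for ordinal in range(n_rep - 1):
            L = _sample_spacer_length(params, rng)
            target = None
            strand = "+"
            mism = 0
            pos = 0
            if rng.random() < params.frac_mge_spacers:
                target = mge_ids[int(rng.integers(len(mge_ids)))]
                genome = mge_pool[target]
                pos = int(rng.integers(0, len(genome) - L + 1))
                proto = genome[pos : pos + L]
                strand = "+" if rng.random() < 0.5 else "-"
                spacer = proto if strand == "+" else revcomp(proto)
                m_lo = int(np.ceil((1.0 - id_hi) * L - 1e-9))
                m_hi = int(np.floor((1.0 - id_lo) * L + 1e-9))
                mism = int(rng.integers(m_lo, m_hi + 1))
                spacer = _mutate_dna(rng, spacer, mism)
            else:
                spacer = random_dna(rng, L, params.gc_content)
            spacer_infos.append(
                dict(seq=spacer, target=target, strand=strand, pos=pos, mism=mism, L=L)
            )
        arrays_seq.append(
            "".join(
                instances[i] + (spacer_infos[i]["seq"] if i < len(spacer_infos) else "")
                for i in range(n_rep)
            )
        )
        arrays_meta.append((rep_id, rep_seq, [len(s) for s in instances], spacer_infos))

    # splice arrays at sorted random cut points in the background
    cuts = sorted(int(x) for x in rng.integers(1000, len(background) - 1000, size=len(arrays_seq)))
    genome_parts: list[str] = []
    host_arrays: list[HostArrayRecord] = []
    prev = 0
    offset = 0
    for ai, (cut, arr_seq) in enumerate(zip(cuts, arrays_seq)):
        genome_parts.append(background[prev:cut])
        arr_start = cut + offset
        rep_id, rep_seq, inst_lens, spacer_infos = arrays_meta[ai]
        repeat_starts: list[int] = []
        spacer_ids: list[str] = []
        p = arr_start
        for i, ilen in enumerate(inst_lens):
            repeat_starts.append(p)
            p += ilen
            if i < len(spacer_infos):
                info = spacer_infos[i]
                sid = f"tsp{spacer_counter:05d}"
                spacer_counter += 1
                spacer_ids.append(sid)
                all_spacers.append(
                    SpacerTruth(sid, info["seq"], host_id, ai, i, p, p + info["L"], info["target"])
                )
                if info["target"] is not None:
                    all_protos.append(
                        ProtospacerRecord(
                            sid, info["target"], info["pos"], info["pos"] + info["L"],
                            info["strand"], info["mism"],
                        )
                    )
                p += info["L"]
        host_arrays.append(
            HostArrayRecord(host_id, ai, arr_start, p, rep_id, rep_seq, repeat_starts, spacer_ids)
        )
        genome_parts.append(arr_seq)
        offset += len(arr_seq)
        prev = cut
    genome_parts.append(background[prev:])
    return "".join(genome_parts), host_arrays, all_spacers, all_protos


def _tile(
    rng: np.random.Generator, length: int, mean: int, min_len: int
) -> list[tuple[int, int]]:
    """Cut [0, length) into consecutive gap-free fragments around ``mean``."""
    if length <= mean + min_len:
        return [(0, length)]
    pieces: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        flen = int(max(min_len, rng.normal(mean, mean / 4.0)))
        if length - pos - flen < min_len:
            flen = length - pos
        pieces.append((pos, pos + flen))
        pos += flen
    return pieces


def generate_metagenome(
    params: SimParams,
    hosts: dict[str, str],
    mge_pool: dict[str, str],
    mge_records: list[MgeRecord],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[ContigRecord]]:
    """Assemble the contig set: host fragments, MGE contigs, random decoys.

    Complete MGEs (with a terminal repeat) are emitted whole; linear
    fragments longer than the fragmentation scale are tiled into consecutive
    pieces.  Decoys are i.i.d. random sequence at the configured GC.
    """
    if not hosts or not mge_pool:
        raise ValueError("need at least one host and one MGE")
    contigs: dict[str, str] = {}
    records: list[ContigRecord] = []
    counter = 0

    def emit(seq: str, origin: str, source_id: str, s: int, e: int) -> None:
        nonlocal counter
        cid = f"ctg{counter:05d}"
        counter += 1
        contigs[cid] = seq
        records.append(ContigRecord(cid, origin, source_id, s, e))

    for hid in hosts:
        seq = hosts[hid]
        for s, e in _tile(rng, len(seq), params.contig_fragmentation, params.min_fragment_length):
            emit(seq[s:e], "host", hid, s, e)

    complete = {m.mge_id for m in mge_records if m.completeness != "linear-fragment"}
    for mid in mge_pool:
        seq = mge_pool[mid]
        if mid in complete:
            emit(seq, "mge", mid, 0, len(seq))
        else:
            for s, e in _tile(rng, len(seq), params.contig_fragmentation, params.min_fragment_length):
                emit(seq[s:e], "mge", mid, s, e)

    lo, hi = params.decoy_length_range
    for _ in range(params.n_decoys):
        L = int(rng.integers(lo, hi + 1))
        seq = random_dna(rng, L, params.gc_content)
        cid = f"ctg{counter:05d}"
        counter += 1
        contigs[cid] = seq
        records.append(ContigRecord(cid, "decoy", cid, 0, L))
    return contigs, records


@dataclass
class SimResult:
    """Everything one simulated scenario emits."""

    params: SimParams
    reference_repeats: dict[str, str]
    hosts: dict[str, str]
    mges: dict[str, str]
    contigs: dict[str, str]
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "reference_repeats.fasta", self.reference_repeats)
        write_fasta(outdir / "hosts.fasta", self.hosts)
        write_fasta(outdir / "mges.fasta", self.mges)
        write_fasta(outdir / "contigs.fasta", self.contigs)
        self.manifest.to_json(outdir / "manifest.json")
        self.manifest.to_tsv(outdir / "manifest.tsv")
        self.params.to_file(outdir / "sim_params.cfg")


def simulate(params: SimParams) -> SimResult:
    """Run the full generator: repeats -> MGE families -> hosts -> metagenome."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    repeats = generate_repeat_family(params, rng)
    manifest = TruthManifest(params=params)

    mge_pool: dict[str, str] = {}
    for f in range(params.n_mge_families):
        genomes, records = generate_mge_family(params, rng, family_id=f"fam{f:02d}")
        mge_pool.update(genomes)
        manifest.mges.extend(records)

    hosts: dict[str, str] = {}
    spacer_counter = 0
    for h in range(params.n_hosts):
        hid = f"host{h:02d}"
        genome, arrays, spacers, protos = generate_host_genome(
            params, mge_pool, rng, host_id=hid,
            reference_repeats=repeats, spacer_start_index=spacer_counter,
        )
        spacer_counter += len(spacers)
        hosts[hid] = genome
        manifest.host_arrays.extend(arrays)
        manifest.spacers.extend(spacers)
        manifest.protospacers.extend(protos)

    contigs, contig_records = generate_metagenome(params, hosts, mge_pool, manifest.mges, rng)
    manifest.contigs = contig_records
    return SimResult(params, dict(repeats), hosts, mge_pool, contigs, manifest)
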
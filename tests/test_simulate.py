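"""Generator self-consistency: every manifest claim is re-verifiable from the
emitted sequences by independent brute-force checks."""

from __future__ import annotations

import json

import numpy as np
import pytest

import ventmge as v
from oracles import oracle_search
from ventmge.genes import _make_aligner, alignment_identity_coverage
from ventmge.seqs import hamming, revcomp
from ventmge.simulate import _tile


def test_seed_determinism(small_params, small_sim):
    """Identical SimParams produce byte-identical sequences and manifest."""
    again = v.simulate(small_params)
    assert again.contigs == small_sim.contigs
    assert again.hosts == small_sim.hosts
    assert again.reference_repeats == small_sim.reference_repeats
    assert json.dumps(again.manifest._as_dict()) == json.dumps(small_sim.manifest._as_dict())


class TestRepeatFamily:
    def test_single_draw(self):
        params = v.SimParams(repeat_length_range=(30, 30))
        rng = np.random.default_rng(0)
        fam = v.generate_repeat_family(params, rng, n=1)
        assert len(fam) == 1
        assert len(fam[0][1]) == 30
        assert set(fam[0][1]) <= set("ACGT")

    def test_determinism(self):
        params = v.SimParams(seed=7)
        a = v.generate_repeat_family(params, np.random.default_rng(7), n=5)
        b = v.generate_repeat_family(params, np.random.default_rng(7), n=5)
        assert a == b

    def test_pairwise_hamming_floor(self):
        """Equal-length reference repeats differ at >= 3 positions (all pairs)."""
        fam = v.generate_repeat_family(v.SimParams(), np.random.default_rng(1), n=8)
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                a, b = fam[i][1], fam[j][1]
                if len(a) == len(b):
                    assert hamming(a, b) >= 3

    def test_unsatisfiable_raises(self, monkeypatch):
        """Bounded retries end in a generation error when the pairwise
        distance floor cannot be met (forced by a degenerate base sampler)."""
        import sys

        sim_mod = sys.modules["ventmge.simulate"]
        monkeypatch.setattr(sim_mod, "random_dna", lambda rng, n, gc=0.5: "A" * n)
        params = v.SimParams(repeat_length_range=(30, 30))
        with pytest.raises(v.GenerationError):
            v.generate_repeat_family(params, np.random.default_rng(0), n=2)


class TestMgeFamily:
    def test_core_modules_shared_and_diverged(self):
        """Every member pair shares >= 6 ORF pairs at >= 40% aa identity."""
        params = v.SimParams(mges_per_family=3, n_core_modules=6)
        genomes, records = v.generate_mge_family(params, np.random.default_rng(5))
        aligner = _make_aligner()
        proteins: dict[str, dict[str, str]] = {}
        for rec in records:
            proteins[rec.mge_id] = {}
            for g in rec.genes:
                if g.kind != "core":
                    continue
                nt = genomes[rec.mge_id][g.start : g.end]
                if g.strand == "-":
                    nt = revcomp(nt)
                from Bio.Seq import Seq

                proteins[rec.mge_id][g.module_id] = "M" + str(Seq(nt[:-3]).translate(table=11))[1:]
        ids = list(proteins)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                shared = 0
                for mod in proteins[ids[i]]:
                    ident, _ca, _cb = alignment_identity_coverage(
                        aligner, proteins[ids[i]][mod], proteins[ids[j]][mod]
                    )
                    if ident >= 0.40:
                        shared += 1
                assert shared >= 6

    def test_all_complete_have_verifiable_terminal_repeats(self):
        params = v.SimParams(frac_complete_mges=1.0, mges_per_family=4)
        genomes, records = v.generate_mge_family(params, np.random.default_rng(2))
        for rec in records:
            seq = genomes[rec.mge_id]
            L = rec.tr_length
            assert L >= 20
            if rec.completeness == "DTR":
                assert seq[:L] == seq[-L:]
            else:
                assert rec.completeness == "ITR"
                assert seq[:L] == revcomp(seq[-L:])

    def test_zero_divergence_limit(self):
        """Identity target 1.0 leaves shared modules identical across members."""
        params = v.SimParams(core_identity_range=(1.0, 1.0), mges_per_family=3)
        genomes, records = v.generate_mge_family(params, np.random.default_rng(9))
        by_module: dict[str, set[str]] = {}
        for rec in records:
            for g in rec.genes:
                if g.kind != "core":
                    continue
                nt = genomes[rec.mge_id][g.start : g.end]
                if g.strand == "-":
                    nt = revcomp(nt)
                from Bio.Seq import Seq

                by_module.setdefault(g.module_id, set()).add(str(Seq(nt[:-3]).translate(table=11))[1:])
        for mod, prots in by_module.items():
            assert len(prots) == 1, f"module {mod} not identical across members"

    def test_planted_genes_are_valid_orfs(self, small_sim):
        """Recorded gene spans start with a start codon, end with an in-frame
        stop, contain no internal stop, and encode >= 60 residues."""
        stops = {"TAA", "TAG", "TGA"}
        starts = {"ATG", "GTG", "TTG"}
        for rec in small_sim.manifest.mges:
            seq = small_sim.mges[rec.mge_id]
            for g in rec.genes:
                nt = seq[g.start : g.end]
                if g.strand == "-":
                    nt = revcomp(nt)
                assert len(nt) % 3 == 0
                assert nt[:3] in starts
                assert nt[-3:] in stops
                codons = [nt[i : i + 3] for i in range(0, len(nt) - 3, 3)]
                assert not any(c in stops for c in codons)
                assert len(codons) >= 60


class TestHostGenome:
    def test_fencepost_and_planted_sequences(self, small_sim):
        """n repeats bracket exactly n-1 spacers, and every recorded repeat
        and spacer is present at its coordinates in the emitted genome."""
        spacers = {s.spacer_id: s for s in small_sim.manifest.spacers}
        for arr in small_sim.manifest.host_arrays:
            assert len(arr.repeat_starts) == len(arr.spacer_ids) + 1
            host = small_sim.hosts[arr.host_id]
            for rs in arr.repeat_starts:
                inst = host[rs : rs + len(arr.repeat_seq)]
                assert hamming(inst, arr.repeat_seq) <= 1
            for sid in arr.spacer_ids:
                s = spacers[sid]
                assert host[s.start : s.end] == s.sequence

    def test_protospacer_mismatches_recomputable(self, small_sim):
        """Recorded mismatch counts equal the Hamming distance between the
        emitted spacer and its protospacer window, re-derived from scratch."""
        spacers = {s.spacer_id: s.sequence for s in small_sim.manifest.spacers}
        assert small_sim.manifest.protospacers
        for p in small_sim.manifest.protospacers:
            window = small_sim.mges[p.mge_id][p.start : p.end]
            oriented = spacers[p.spacer_id] if p.strand == "+" else revcomp(spacers[p.spacer_id])
            assert hamming(oriented, window) == p.mismatches

    def test_identity_controllability(self, small_sim):
        """No planted protospacer identity falls outside the requested range."""
        lo, hi = small_sim.params.protospacer_identity_range
        for p in small_sim.manifest.protospacers:
            L = p.end - p.start
            identity = (L - p.mismatches) / L
            assert lo - 1e-12 <= identity <= hi + 1e-12

    def test_exact_identity_forces_zero_mismatches(self):
        params = v.SimParams(
            seed=11, protospacer_identity_range=(1.0, 1.0), frac_mge_spacers=1.0,
            n_hosts=1, n_mge_families=1, mges_per_family=2, n_decoys=0,
            host_genome_length=15_000,
        )
        sim = v.simulate(params)
        assert sim.manifest.protospacers
        assert all(p.mismatches == 0 for p in sim.manifest.protospacers)
        assert all(s.target_mge is not None for s in sim.manifest.spacers)

    def test_spacer_length_distribution(self, small_sim):
        lengths = [s.end - s.start for s in small_sim.manifest.spacers]
        lo, hi = small_sim.params.spacer_length_range
        assert all(lo <= L <= hi for L in lengths)
        assert abs(float(np.median(lengths)) - 37.0) <= 2.0


class TestMetagenome:
    def test_single_complete_mge_single_contig(self):
        params = v.SimParams(
            seed=5, n_hosts=1, n_mge_families=1, mges_per_family=1,
            frac_complete_mges=1.0, n_decoys=0, host_genome_length=12_000,
            contig_fragmentation=50_000,
        )
        sim = v.simulate(params)
        mge_contigs = [c for c in sim.manifest.contigs if c.origin == "mge"]
        assert len(mge_contigs) == 1
        c = mge_contigs[0]
        assert sim.contigs[c.contig_id] == sim.mges[c.source_id]
        assert (c.source_start, c.source_end) == (0, len(sim.mges[c.source_id]))

    def test_fragments_tile_without_gaps(self, rng):
        """Tiling a 12 kbp source at ~3 kbp covers it exactly, gap-free."""
        pieces = _tile(rng, 12_000, 3_000, 500)
        assert pieces[0][0] == 0 and pieces[-1][1] == 12_000
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2
        assert all(e > s for s, e in pieces)

    def test_contig_records_match_sources(self, small_sim):
        sources = {**small_sim.hosts, **small_sim.mges}
        for c in small_sim.manifest.contigs:
            if c.origin in ("host", "mge"):
                assert small_sim.contigs[c.contig_id] == sources[c.source_id][c.source_start : c.source_end]
            else:
                assert c.origin == "decoy"
        ids = [c.contig_id for c in small_sim.manifest.contigs]
        assert len(ids) == len(set(ids))

    def test_decoys_contain_no_planted_protospacers(self, small_sim):
        """Brute-force scan: no spacer matches any decoy at >= 90% identity."""
        decoys = {
            c.contig_id: small_sim.contigs[c.contig_id]
            for c in small_sim.manifest.contigs
            if c.origin == "decoy"
        }
        for s in small_sim.manifest.spacers:
            assert oracle_search(s.sequence, decoys, 0.90) == []


def test_manifest_round_trips(tmp_path, small_sim):
    small_sim.manifest.to_json(tmp_path / "m.json")
    back = v.TruthManifest.from_json(tmp_path / "m.json")
    assert back._as_dict() == small_sim.manifest._as_dict()
    small_sim.manifest.to_tsv(tmp_path / "m.tsv")
    text = (tmp_path / "m.tsv").read_text()
    for section in ("## mges", "## protospacers", "## contigs"):
        assert section in text


def test_params_config_round_trip(tmp_path):
    params = v.SimParams(seed=9, n_decoys=7, protospacer_identity_range=(0.92, 0.97))
    params.to_file(tmp_path / "p.cfg")
    assert v.SimParams.from_file(tmp_path / "p.cfg") == params


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        v.SimParams(frac_complete_mges=1.5).validate()
    with pytest.raises(ValueError):
        v.SimParams(protospacer_identity_range=(0.95, 0.5)).validate()
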
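"""End-to-end orchestration: mine -> search -> select -> dedup -> network.

`run_pipeline` composes the discovery stages over a contig set, a reference
repeat set, and (optionally) host isolate genomes, writing every
intermediate to the output directory so each summary statistic can be
recomputed from files.  Identical configuration and inputs produce
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as vio
from .arrays import (
    CrisprArray,
    DetectParams,
    Spacer,
    anchor_arrays,
    dedup_spacers,
    detect_arrays,
    extract_spacers,
)
from .genes import (
    GeneSharingGraph,
    build_network,
    call_orfs,
    cluster_proteins,
    core_clusters,
    detect_communities,
    select_representatives,
    targeting_density,
)
from .protospacers import index_contigs, mask_array_hits, search_spacers
from .selection import (
    CompletenessCall,
    dedup_candidates,
    find_terminal_repeats,
    screen_against_hosts,
    select_candidates,
)
from .seqs import read_fasta, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds plus input paths and the seed.

    Defaults are the discovery procedure's published operating point:
    29-31 nt repeats anchored at <=1 mismatch, protospacer hits at >=90%
    identity, candidates >=2 kbp with >=2 hits (or 1 hit plus a terminal
    repeat >=20 bp at <=10% mismatches), dereplication at >=98% ANI / >=95%
    coverage, protein clustering at 25% identity, network edges at >=5
    shared clusters, representatives at >=75% of the shortest complete
    genome.
    """

    contigs: str = ""
    reference_repeats: str = ""
    host_genomes: str = ""
    spacer_fasta: str = ""  # optional precomputed spacers
    seed: int = 42
    # array detection
    repeat_min_len: int = 29
    repeat_max_len: int = 31
    array_min_spacer: int = 20
    array_max_spacer: int = 60
    array_min_repeats: int = 3
    array_max_divergence: int = 2
    array_seed_k: int = 8
    anchor_max_mismatches: int = 1
    # protospacer search
    search_seed_k: int = 7
    min_identity: float = 0.90
    # candidate selection
    min_len: int = 2000
    min_hits: int = 2
    # terminal repeats
    tr_min_len: int = 20
    tr_max_mismatch_frac: float = 0.10
    tr_window: int = 2000
    # dereplication
    dedup_min_ani: float = 0.98
    dedup_min_cov: float = 0.95
    # host screen
    host_screen_ani: float = 0.98
    host_screen_cov: float = 0.50
    # gene sharing
    orf_min_aa: int = 60
    cluster_min_identity: float = 0.25
    cluster_min_cov: float = 0.80
    min_shared_clusters: int = 5
    core_min_frac: float = 0.80
    representative_min_frac: float = 0.75

    def detect_params(self) -> DetectParams:
        return DetectParams(
            min_repeat_len=self.repeat_min_len,
            max_repeat_len=self.repeat_max_len,
            min_spacer_len=self.array_min_spacer,
            max_spacer_len=self.array_max_spacer,
            min_repeats=self.array_min_repeats,
            max_divergence=self.array_max_divergence,
            seed_k=self.array_seed_k,
        )

    def validate(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.repeat_min_len > self.repeat_max_len:
            raise ValueError("repeat length window inverted")
        if self.min_len < 0 or self.min_hits < 1:
            raise ValueError("invalid selection thresholds")
        for name in ("dedup_min_ani", "dedup_min_cov", "cluster_min_identity",
                     "cluster_min_cov", "core_min_frac", "representative_min_frac",
                     "tr_max_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
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
            if f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)


@dataclass
class RunSummary:
    """Per-stage counts and derived statistics of one pipeline run."""

    n_contigs: int = 0
    arrays_contigs: int = 0
    arrays_contigs_anchored: int = 0
    arrays_isolates: int = 0
    unique_spacers: int = 0
    spacers_with_hits: int = 0
    spacer_match_fraction: float = 0.0
    hits_total: int = 0
    hits_masked: int = 0
    candidates_total: int = 0
    candidates_multi_hit: int = 0
    candidates_single_hit_complete: int = 0
    candidates_host_flagged: int = 0
    complete_genomes: int = 0
    dedup_clusters: int = 0
    network_nodes: int = 0
    network_edges: int = 0
    communities: int = 0
    mean_hits_per_candidate: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def check_consistency(self) -> None:
        assert self.arrays_contigs_anchored <= self.arrays_contigs
        assert self.spacers_with_hits <= self.unique_spacers
        assert self.candidates_total <= self.n_contigs
        assert self.dedup_clusters <= self.candidates_total
        assert (
            self.candidates_multi_hit + self.candidates_single_hit_complete
            == self.candidates_total
        )


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    summary: RunSummary
    contigs: dict[str, str]
    catalog: list[Spacer]
    hits: list
    contig_arrays: list[CrisprArray]
    isolate_arrays: list[CrisprArray]
    completeness: dict[str, CompletenessCall]
    candidates: list
    clusters: list
    gsg: GeneSharingGraph | None
    communities: dict[str, int]


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages and write every intermediate under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.cfg")

    for path, label in ((config.contigs, "contigs"), (config.reference_repeats, "reference_repeats")):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing {label} FASTA: {path!r}")
    contigs = read_fasta(config.contigs)
    references = list(read_fasta(config.reference_repeats).items())
    hosts = read_fasta(config.host_genomes) if config.host_genomes else {}

    dp = config.detect_params()
    summary = RunSummary(n_contigs=len(contigs))

    # --- stage 1: CRISPR mining -------------------------------------------
    isolate_arrays: list[CrisprArray] = []
    for hid, seq in hosts.items():
        isolate_arrays.extend(detect_arrays(seq, dp, contig_id=hid))
    anchor_arrays(isolate_arrays, references, config.anchor_max_mismatches)

    contig_arrays: list[CrisprArray] = []
    for cid, seq in contigs.items():
        if len(seq) >= 2 * dp.min_repeat_len:
            contig_arrays.extend(detect_arrays(seq, dp, contig_id=cid))
    anchor_arrays(contig_arrays, references, config.anchor_max_mismatches)

    raw_spacers = extract_spacers(isolate_arrays, "isolate_genome")
    raw_spacers += extract_spacers(contig_arrays, "metagenome")
    if config.spacer_fasta:
        for sid, seq in read_fasta(config.spacer_fasta).items():
            raw_spacers.append(
                Spacer("", seq, len(seq), [(sid, f"{config.spacer_fasta}:{sid}", 0)], "isolate_genome")
            )
    catalog = dedup_spacers(raw_spacers)

    summary.arrays_isolates = len(isolate_arrays)
    summary.arrays_contigs = len(contig_arrays)
    summary.arrays_contigs_anchored = sum(a.anchored for a in contig_arrays)
    summary.unique_spacers = len(catalog)
    vio.write_arrays_gff3(outdir / "arrays.gff3", isolate_arrays + contig_arrays)
    vio.write_spacer_catalog(outdir / "spacers.fasta", outdir / "spacers.tsv", catalog)

    # --- stage 2: protospacer search --------------------------------------
    index = index_contigs(contigs, config.search_seed_k)
    all_hits = search_spacers(catalog, contigs, index, config.min_identity)
    hits, n_masked = mask_array_hits(all_hits, contig_arrays)
    summary.hits_total = len(hits)
    summary.hits_masked = n_masked
    summary.spacers_with_hits = len({h.spacer_id for h in hits})
    summary.spacer_match_fraction = (
        summary.spacers_with_hits / summary.unique_spacers if catalog else 0.0
    )
    vio.write_tsv(outdir / "hits.tsv", vio.hits_frame(hits))
    vio.write_hits_bed(outdir / "hits.bed", hits)

    # --- stage 3: completeness + selection --------------------------------
    hit_contigs = sorted({h.contig_id for h in hits})
    completeness: dict[str, CompletenessCall] = {}
    for cid in hit_contigs:
        if len(contigs[cid]) >= config.min_len:
            completeness[cid] = find_terminal_repeats(
                contigs[cid], cid, config.tr_min_len,
                config.tr_max_mismatch_frac, config.tr_window,
            )
    candidates = select_candidates(
        contigs, hits, completeness, config.min_len, config.min_hits, config.min_identity
    )
    if hosts:
        screen_against_hosts(
            candidates, contigs, hosts, config.host_screen_ani, config.host_screen_cov
        )
    summary.candidates_total = len(candidates)
    summary.candidates_multi_hit = sum(c.selection_branch == "multi_hit" for c in candidates)
    summary.candidates_single_hit_complete = sum(
        c.selection_branch == "single_hit_complete" for c in candidates
    )
    summary.candidates_host_flagged = sum(c.host_flagged for c in candidates)
    summary.complete_genomes = sum(c.completeness.is_complete for c in candidates)
    summary.mean_hits_per_candidate = (
        sum(c.n_hits for c in candidates) / len(candidates) if candidates else 0.0
    )
    vio.write_tsv(
        outdir / "completeness.tsv",
        pd.DataFrame(
            [
                {
                    "contig_id": c.contig_id, "kind": c.kind,
                    "repeat_length": c.repeat_length, "mismatches": c.mismatches,
                    "mismatch_fraction": round(c.mismatch_fraction, 6),
                }
                for c in completeness.values()
            ],
            columns=["contig_id", "kind", "repeat_length", "mismatches", "mismatch_fraction"],
        ),
    )
    vio.write_tsv(
        outdir / "candidates.tsv",
        pd.DataFrame(
            [
                {
                    "contig_id": c.contig_id, "length": c.length, "n_hits": c.n_hits,
                    "selection_branch": c.selection_branch,
                    "completeness": c.completeness.kind,
                    "host_flagged": c.host_flagged,
                }
                for c in candidates
            ],
            columns=["contig_id", "length", "n_hits", "selection_branch", "completeness", "host_flagged"],
        ),
    )

    # --- stage 4: dereplication -------------------------------------------
    cand_seqs = {c.contig_id: contigs[c.contig_id] for c in candidates}
    clusters = dedup_candidates(cand_seqs, config.dedup_min_ani, config.dedup_min_cov)
    summary.dedup_clusters = len(clusters)
    vio.write_tsv(
        outdir / "dedup_clusters.tsv",
        pd.DataFrame(
            [
                {
                    "representative": cl.representative, "member": m,
                    "ani": round(ani, 6), "coverage": round(cov, 6),
                }
                for cl in clusters
                for m, ani, cov in cl.members
            ],
            columns=["representative", "member", "ani", "coverage"],
        ),
    )
    representatives = {cl.representative: contigs[cl.representative] for cl in clusters}
    write_fasta(outdir / "representatives.fasta", representatives)

    # --- stage 5: gene sharing --------------------------------------------
    orfs = []
    for cid in sorted(representatives):
        orfs.extend(call_orfs(representatives[cid], cid, config.orf_min_aa))
    pclusters = cluster_proteins(
        [(o.orf_id, o.protein) for o in orfs],
        config.cluster_min_identity, config.cluster_min_cov,
    )
    orf_contig = {o.orf_id: o.contig_id for o in orfs}
    contig_clusters: dict[str, list[str]] = {cid: [] for cid in representatives}
    for pc in pclusters:
        for orf_id in pc.members:
            contig_clusters[orf_contig[orf_id]].append(pc.cluster_id)
    gsg = build_network(contig_clusters, config.min_shared_clusters)
    communities = detect_communities(gsg, seed=config.seed)
    summary.network_nodes = gsg.graph.number_of_nodes()
    summary.network_edges = gsg.graph.number_of_edges()
    summary.communities = len(set(communities.values()))

    vio.write_orfs_gff3(outdir / "orfs.gff3", orfs)
    write_fasta(outdir / "proteins.fasta", [(o.orf_id, o.protein) for o in orfs])
    vio.write_tsv(
        outdir / "protein_clusters.tsv",
        pd.DataFrame(
            [
                {"cluster_id": pc.cluster_id, "representative": pc.representative,
                 "n_members": len(pc.members), "members": ";".join(pc.members)}
                for pc in pclusters
            ],
            columns=["cluster_id", "representative", "n_members", "members"],
        ),
    )
    vio.write_network(outdir / "network.tsv", outdir / "network.graphml", gsg.graph)
    vio.write_tsv(
        outdir / "communities.tsv",
        pd.DataFrame(
            sorted(
                ({"contig_id": n, "community": c} for n, c in communities.items()),
                key=lambda r: (r["community"], r["contig_id"]),
            ),
            columns=["contig_id", "community"],
        ),
    )

    # --- stage 6: reports --------------------------------------------------
    write_reports(summary, outdir, contigs, hits, candidates, completeness,
                  contig_clusters, communities, config)
    summary.check_consistency()
    return PipelineResult(
        config=config, summary=summary, contigs=contigs, catalog=catalog,
        hits=hits, contig_arrays=contig_arrays, isolate_arrays=isolate_arrays,
        completeness=completeness, candidates=candidates, clusters=clusters,
        gsg=gsg, communities=communities,
    )


def write_reports(
    summary: RunSummary,
    outdir: Path,
    contigs: dict[str, str],
    hits: list,
    candidates: list,
    completeness: dict[str, CompletenessCall],
    contig_clusters: dict[str, list[str]],
    communities: dict[str, int],
    config: RunConfig,
) -> None:
    """Write the run summary (TSV + JSON) and the per-community table."""
    hits_by_contig: dict[str, list] = {}
    for h in hits:
        hits_by_contig.setdefault(h.contig_id, []).append(h)
    lengths = {cid: len(seq) for cid, seq in contigs.items()}

    members_by_comm: dict[int, list[str]] = {}
    for node, comm in communities.items():
        members_by_comm.setdefault(comm, []).append(node)
    rows = []
    for comm in sorted(members_by_comm):
        members = sorted(members_by_comm[comm])
        core = core_clusters(members, contig_clusters, config.core_min_frac)
        reps, has_complete = select_representatives(
            members, lengths, completeness, config.representative_min_frac
        )
        dens = [
            targeting_density(lengths[m], hits_by_contig.get(m, [])) for m in members
        ]
        n_complete = sum(
            1 for m in members
            if completeness.get(m, CompletenessCall(m, "none")).is_complete
        )
        rows.append(
            {
                "community": comm,
                "size": len(members),
                "n_complete": n_complete,
                "has_complete_genome": has_complete,
                "n_core_clusters": len(core),
                "core_clusters": ";".join(core),
                "representatives": ";".join(reps),
                "mean_targeting_density": round(sum(dens) / len(dens), 6),
                "members": ";".join(members),
            }
        )
    vio.write_tsv(
        outdir / "community_report.tsv",
        pd.DataFrame(rows, columns=[
            "community", "size", "n_complete", "has_complete_genome",
            "n_core_clusters", "core_clusters", "representatives",
            "mean_targeting_density", "members",
        ]),
    )
    d = summary.to_dict()
    (outdir / "summary.json").write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
    vio.write_tsv(
        outdir / "summary.tsv",
        pd.DataFrame([{"statistic": k, "value": v} for k, v in sorted(d.items())],
                     columns=["statistic", "value"]),
    )
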
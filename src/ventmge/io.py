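"""Deterministic writers for pipeline outputs (GFF3, TSV, BED, GraphML)."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .arrays import CrisprArray, Spacer
from .genes import OrfRecord
from .protospacers import ProtospacerHit


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_arrays_gff3(path: str | Path, arrays: list[CrisprArray]) -> None:
    """Arrays as GFF3: one region per array, one feature per repeat/spacer."""
    lines = ["##gff-version 3"]
    for ai, arr in enumerate(arrays):
        locus = f"array{ai:04d}"
        anchor = (
            f";anchor={arr.anchor_repeat_id};anchor_orientation={arr.anchor_orientation}"
            f";anchor_distance={arr.anchor_distance}"
            if arr.anchored
            else ""
        )
        lines.append(
            "\t".join(
                [
                    arr.contig_id, "ventmge", "CRISPR",
                    str(arr.start + 1), str(arr.end), ".", ".", ".",
                    f"ID={locus};consensus={arr.repeat_consensus}{anchor}",
                ]
            )
        )
        for ri, (s, seq) in enumerate(arr.repeat_instances):
            lines.append(
                "\t".join(
                    [
                        arr.contig_id, "ventmge", "direct_repeat",
                        str(s + 1), str(s + len(seq)), ".", ".", ".",
                        f"ID={locus}.rep{ri};Parent={locus}",
                    ]
                )
            )
        for si, (s, e, _seq) in enumerate(arr.spacers):
            lines.append(
                "\t".join(
                    [
                        arr.contig_id, "ventmge", "spacer",
                        str(s + 1), str(e), ".", ".", ".",
                        f"ID={locus}.sp{si};Parent={locus}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_spacer_catalog(fasta_path: str | Path, tsv_path: str | Path, catalog: list[Spacer]) -> None:
    with open(fasta_path, "w") as fh:
        for sp in catalog:
            first = sp.sources[0]
            fh.write(f">{sp.spacer_id} {first[1]}.{first[2]} {sp.origin_class}\n{sp.sequence}\n")
    rows = [
        {
            "spacer_id": sp.spacer_id,
            "length": sp.length,
            "origin_class": sp.origin_class,
            "n_sources": len(sp.sources),
            "sources": ";".join(f"{c}|{l}|{o}" for c, l, o in sp.sources),
            "sequence": sp.sequence,
        }
        for sp in catalog
    ]
    write_tsv(tsv_path, pd.DataFrame(rows, columns=[
        "spacer_id", "length", "origin_class", "n_sources", "sources", "sequence"
    ]))


def hits_frame(hits: list[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "contig_id": h.contig_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "identity": round(h.identity, 6),
            }
            for h in hits
        ],
        columns=["spacer_id", "contig_id", "start", "end", "strand", "mismatches", "identity"],
    )


def write_hits_bed(path: str | Path, hits: list[ProtospacerHit]) -> None:
    lines = [
        "\t".join([h.contig_id, str(h.start), str(h.end), h.spacer_id, str(h.mismatches), h.strand])
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_orfs_gff3(path: str | Path, orfs: list[OrfRecord]) -> None:
    lines = ["##gff-version 3"]
    for o in orfs:
        lines.append(
            "\t".join(
                [
                    o.contig_id, "ventmge", "CDS",
                    str(o.start + 1), str(o.end), ".", o.strand, "0",
                    f"ID={o.orf_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_network(tsv_path: str | Path, graphml_path: str | Path, graph: nx.Graph) -> None:
    rows = [
        {"contig_a": a, "contig_b": b, "shared_clusters": d["shared"], "weight": d["weight"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    write_tsv(tsv_path, pd.DataFrame(rows, columns=["contig_a", "contig_b", "shared_clusters", "weight"]))
    nx.write_graphml(graph, str(graphml_path))
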
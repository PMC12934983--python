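# ventmge

CRISPR-spacer-guided discovery of mobile genetic elements (MGEs) and viruses
of **Thermococcales** — hyperthermophilic archaea of deep-sea hydrothermal
vents — from metagenome contigs.

Most viruses of vent archaea have no cultivated representative and no close
relative in reference databases, so homology search alone cannot find them.
CRISPR arrays solve this: each spacer in a host array is a sequence-identical
record of a past infection, and a match between a host-derived spacer and a
metagenome contig (a *protospacer*) links that contig to the host lineage.
`ventmge` implements this discovery procedure as a tested, reusable pipeline:

1. **CRISPR mining** — repeat-spacer arrays are detected de novo
   (seed-and-extend, repeats restricted to the Thermococcales window of
   29–31 nt) and anchored to a reference repeat set at ≤1 mismatch on either
   strand; spacers from anchored arrays form a deduplicated catalog.
2. **Protospacer search** — every spacer is searched against the contigs in
   both orientations; a hit is a full-length ungapped match at ≥90% identity,
   i.e. mismatches ≤ ⌊0.1·L⌋ for a spacer of length L. Hits inside detected
   arrays are masked as self-matches.
3. **Candidate selection with completeness calling** — a contig ≥2 kbp is a
   candidate MGE if it has ≥2 protospacer hits, or ≥1 hit plus a terminal
   repeat predicting a complete genome: an end-anchored direct (DTR) or
   inverted (ITR) terminal repeat ≥20 bp with ≤10% mismatches.
4. **Dereplication** — candidates are clustered greedily at ≥98% ANI and
   ≥95% coverage of the shorter sequence; ANI is computed by chaining
   maximal exact matches and closing gaps with global alignment.
5. **Gene-sharing network** — ORFs (six-frame, table 11) are clustered at
   25% amino-acid identity with 80% bidirectional coverage; contigs sharing
   ≥5 protein clusters are connected, weighted by the total number of shared
   genes Σ_c min(count_i(c), count_j(c)); seeded weighted-modularity
   (Louvain) communities approximate virus families. Per community the
   pipeline reports core gene clusters, representative genomes (members
   ≥75% of the shortest complete genome), and spacer-targeting density
   (distinct spacers per kbp, a proxy for immune pressure).

Because the original study's inputs are ~220 Gbp of external metagenomes, a
seeded **synthetic-metagenome generator** stands in for them: host genomes
carrying CRISPR arrays, MGE families sharing diverged protein-coding core
modules, protospacers planted at controlled identity, terminal repeats, and
random decoy contigs — all recorded in a machine-readable truth manifest so
every stage is testable without any download.

## Worked example

```python
import ventmge as v

sim = v.simulate(v.SimParams(seed=1))     # 5 MGE families x 4 members,
sim.write("scenario")                     # 3 hosts, ~490 contigs

cfg = v.RunConfig(
    contigs="scenario/contigs.fasta",
    reference_repeats="scenario/reference_repeats.fasta",
    host_genomes="scenario/hosts.fasta",
    seed=1,
)
result = v.run_pipeline(cfg, "run")
s = result.summary
print(s.unique_spacers, s.hits_total, s.candidates_total,
      s.complete_genomes, s.communities)
```

prints

```
114 84 20 9 5
```

meaning: the three hosts' arrays yield 114 unique spacers; after masking
array self-matches, 84 protospacer hits remain on the contigs; exactly the
20 planted MGE contigs pass the selection rule (no decoy does); 9 carry a
terminal repeat and are called complete genomes; and the gene-sharing
network resolves the candidates into 5 communities — one per planted family.
`run/` then contains every intermediate (arrays as GFF3, spacer catalog,
hits TSV/BED, completeness and candidate tables, dereplication clusters,
ORFs, protein clusters, the network as TSV/GraphML, and a per-community
report with core clusters, representatives and targeting densities).

The same pipeline runs from a shell:

```sh
ventmge simulate --seed 1 --out scenario
ventmge run-all --contigs scenario/contigs.fasta \
    --repeats scenario/reference_repeats.fasta \
    --genomes scenario/hosts.fasta --seed 1 --out run
```

Subcommands `mine`, `search`, `completeness` and `dedup` expose the stages
individually.

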
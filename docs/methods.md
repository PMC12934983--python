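# Methods

This note documents the models and algorithmic contracts behind `ventmge`:
what each stage computes, the tunable parameters and their defaults, what
the synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The discovery model

CRISPR arrays are genomic loci of near-identical repeats (29–31 nt in
Thermococcales) alternating with unique spacers acquired from mobile
genetic elements (MGEs). A spacer matching a metagenome contig at high
identity (a protospacer match) is evidence that the contig derives from an
element that infected the host lineage. The pipeline operationalises this
as: mine arrays → restrict to the host lineage via a reference repeat set →
search spacers against contigs → select candidate MGEs → dereplicate →
classify by gene sharing.

## Array detection (`ventmge.arrays`)

Detection is an exact k-mer seed-and-extend scan, in the spirit of CRT and
MinCED, with fully specified deterministic semantics so that an exhaustive
brute-force enumerator can reproduce its output exactly:

- **Seeding.** A k-mer (default k=8) recurring at admissible period —
  repeat length + spacer length, i.e. [29+20, 31+60] = [49, 91] nt with the
  default windows — anchors a candidate chain. Seed k-mer groups that also
  recur at *sub-period* spacing (closer than 49 nt) are skipped as
  tandem/micro-repeat ambiguity; this makes successor chains provably
  branch-free (two admissible successors would have to be ≥2× the minimum
  period apart) and a genuine array is still reached through its other
  ~20 seed offsets.
- **Growth.** The repeat window is extended column by column (right, then
  left) while every instance's total mismatch count against the per-column
  majority consensus (ties alphabetical) stays within a divergence budget
  (default ≤2), with a hard cap of max_repeat_len + 2·budget columns.
  Non-ACGT bases never join a consensus, always count as mismatches, and
  extension never crosses a run of more than two of them in one instance.
- **Trimming.** The budget alone systematically over-runs the true
  boundary: a fresh budget of 2 absorbs roughly two random flank columns on
  each side, which would push a 30-nt repeat out of the 29–31 window
  entirely. End columns are therefore trimmed back until the terminal
  column is unanimous across instances. With ≥5 instances the probability
  that a random flank column is unanimous is ≤4⁻⁴, so boundaries are exact
  in practice; arrays of exactly 3 copies have a small (~6%/side) chance of
  a one-column shift, which affects neither anchoring nor downstream hits.
- **Validation and overlap resolution.** A candidate is kept iff repeat
  length ∈ [29, 31], all spacer lengths ∈ [20, 60], and ≥3 copies are
  present. Overlapping candidates are resolved by most instances, then
  longest span, then leftmost start.

Anchoring to the reference repeat set is exact Hamming distance ≤1 on
either strand, equal lengths only (the repeat window is just 3 nt wide, so
indel tolerance would add nothing testable); metagenomic arrays that fail
to anchor contribute no spacers, isolate-genome arrays are kept regardless.
Spacer deduplication is exact-sequence and orientation-sensitive: a spacer
and its reverse complement record distinct acquisition events.

## Protospacer search (`ventmge.protospacers`)

A hit is a **full-length ungapped** match of the spacer (either strand) at
≥90% identity: mismatches ≤ ⌊0.1·L⌋. The search seeds candidate windows by
the pigeonhole scheme — the spacer is split into m+1 disjoint blocks
(m = mismatch budget), each contributing one exact k-mer lookup (default
k=7, the largest admissible value for the shortest 30-nt spacer) — and
verifies every seeded window by direct Hamming comparison. This is provably
equivalent to scanning every (position, strand) pair: any window within
budget leaves at least one block untouched. Identity is defined so that
identity·L + mismatches = L exactly. Hits overlapping any detected array
interval are masked as self-matches. Gapped or partial-length matches are
deliberately out of scope: the ungapped definition is deterministic,
oracle-checkable, and conservative.

## Completeness and selection (`ventmge.selection`)

A contig is complete when it carries an **end-anchored** terminal repeat:
prefix = suffix (DTR) or prefix = reverse complement of suffix (ITR), for
some length ≥20 with mismatch fraction ≤0.10, searched within the first and
last 2,000 bases. DTR candidates are seeded by shared exact 6-mers at a
consistent end-anchored offset — 6 is the pigeonhole-safe seed for the
worst admissible case (a 20-bp repeat with 2 mismatches can have no exact
run longer than 6) — and each candidate length is verified directly. ITR
needs no seeding: its alignment lies on a fixed anti-diagonal, so one
cumulative mismatch scan is exact. The longest qualifying repeat is
reported (DTR preferred on ties); it may extend a few columns past a
planted repeat when chance matches keep the fraction within 10%, which is
the correct reading of the rule. Internal repeats are never completeness
evidence.

Selection applies the two-branch rule with the ≥2 kbp floor on both
branches (the conservative reading): `multi_hit` (≥2 distinct
(spacer, position) hits) or `single_hit_complete` (≥1 hit plus DTR/ITR).

**ANI** is computed by chaining maximal exact matches ≥15 nt (greedy by
descending length, co-linear, non-overlapping), closing inter-anchor gaps
≤500 nt by global alignment (edlib, unit costs), and counting matched over
aligned columns; coverage is aligned residues on the shorter sequence over
its length. Both orientations are tried; internally the pair is put in a
canonical order (length, then lexicographic) so ANI(a,b) ≡ ANI(b,a) exactly
— chain tie-breaking and co-optimal DP paths would otherwise not guarantee
match-count symmetry. Accuracy is bounded in tests against whole-sequence
DP identity (±0.005 at 0–5% divergence). Dereplication is greedy by
descending length at ≥98% ANI / ≥95% coverage, representative = longest
member; re-running it on the representatives returns all singletons.

The study's manual curation of "likely host genome fragments" is replaced
by an explicit rule: a candidate reaching ≥98% ANI and ≥50% coverage
against a supplied host genome is *flagged*, never silently dropped.

## Gene sharing and communities (`ventmge.genes`)

ORF calling is a deterministic six-frame longest-ORF scan (start codons
ATG/GTG/TTG, stops TAA/TAG/TGA, translation table 11, alternative starts
translated as M, minimum 60 aa, only ORFs with a stop codon) — not a
statistical gene finder. Synthetic genes are constructed to be discoverable
by exactly this rule, which keeps the stage desk-verifiable.

Protein clustering is greedy and incremental: proteins visited by
descending length, each aligned globally (BLOSUM62, gap open 11, extend 1)
against every existing representative, joining the **highest-identity**
cluster that reaches ≥25% identity with ≥80% coverage of both sequences
*and a positive alignment score*. Two guards beyond the raw thresholds keep
spurious joins out. Best-hit rather than first-hit assignment: at a floor
as low as 25%, chance qualifications against unrelated representatives are
not rare, and first-hit joining scatters genuine homolog groups across
them. And the positive-score gate: unrelated ~100-aa proteins occasionally
reach 25% column identity, but their global BLOSUM62 scores remain negative
(random residue pairs score below zero on average) while genuine homologs
score far above — the same role significance thresholds play in dedicated
clustering tools, where identity cutoffs apply only to already-significant
matches. Identity's denominator is all alignment columns including gaps;
coverage counts residues in residue-to-residue columns.

The network connects contigs sharing ≥5 distinct protein clusters, with
edge weight Σ_c min(count_i(c), count_j(c)) — "total shared genes",
formalised symmetrically so it reduces to the shared-cluster count for
single-copy genes. Communities come from seeded weighted-modularity
optimisation (Louvain, deterministic node ordering); overlapping
significance-based community detection (OSLOM-style) is not reproduced,
and community quality is judged by planted-partition recovery instead.
Per community: core clusters (present in ≥80% of members — the prevalence
threshold is a package choice, configurable), representatives (≥75% of the
shortest complete member; a community with no complete member is flagged
rather than assigned), and targeting density (distinct spacers per kbp).

## The synthetic generator (`ventmge.simulate`)

The generator emulates the statistical structure the analysis assumes, with
all randomness flowing from one seeded `numpy` generator (identical
parameters ⇒ byte-identical output):

- **Background** is i.i.d. uniform DNA at configurable GC (default 0.45,
  Thermococcales-like): the simplest null under which spurious ≥20 bp
  end-anchored repeats and spurious ≥90% spacer matches are vanishingly
  improbable, so decoys are clean negatives by construction.
- **Reference repeats**: 29–31 nt, pairwise Hamming ≥3 between equal-length
  pairs, so the ≤1-mismatch anchor is unambiguous.
- **MGE families** (default 5 × 4 members): each family shares 10 core
  protein modules mutated from a common ancestor toward a per-module target
  identity drawn from 0.45–0.90 — members mutate exactly (1−t)/2 of sites,
  guaranteeing pairwise site identity ≥ t — plus 2–4 member-specific
  accessory ORFs. Genes are 90–200 aa, strand chosen at random, each
  preceded by an in-frame stop so the six-frame caller recovers exactly the
  planted span. Half the members (default) carry a DTR or ITR of 20–60 bp.
- **Hosts** (default 3 × 40 kbp, 2 arrays of 12–25 repeats each): spacer
  lengths follow a discretized normal (median 37 nt, truncated to 30–50,
  matching observed spacer-length distributions); 70% of spacers are
  (possibly mutated) substrings of MGE genomes on either strand, the rest
  are random "dark" spacers. Planted protospacer mismatch counts are drawn
  uniformly over the integers compatible with the requested identity range
  (default 0.90–1.00), so no planted identity falls outside it. One repeat
  instance per array may carry a single interior substitution
  (probability 0.3), exercising the divergence allowance without touching
  the repeat ends the boundary trim relies on.
- **Metagenome** (~490 contigs by default): host genomes and long
  incomplete MGEs are tiled into gap-free fragments around a mean length
  (default 6 kbp, minimum 2.5 kbp, trailing remnants merged); complete MGEs
  are emitted whole; 450 decoys of 2–8 kbp are pure background. The truth
  manifest records the origin and source coordinates of every contig and
  every planted feature, and every claim is re-verifiable from the emitted
  sequences alone.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error and assembly artifacts,
integrase-mediated chromosomal integration, PAM- or strand-biased spacer
acquisition (protospacers are planted uniformly; the source study gives no
acquisition bias to copy), compositional bias/repeats of real genomes, and
gene-content evolution beyond substitution divergence (no rearrangement,
duplication, or indels within core modules). Real metagenomes will yield
lower recall and noisier networks than the synthetic scenario.

## Problem sizes and numerical choices

The default test scenario (5 families × 4 members, 3 hosts, ~490 contigs,
~115 unique spacers) was chosen so the full pipeline, its brute-force
oracles, and ten-seed replication all run comfortably on a single CPU;
stage-level oracle tests use 100 × 50 kbp genomes (arrays), 10,000 cases
(anchoring), ~160 kbp contig sets (search), 1,000 × 10 kbp contigs
(completeness false positives), and 50 pairs ≤10 kbp (ANI). Floating-point
thresholds are compared with a 1e-12 slack so boundary cases (e.g. exactly
2/20 terminal-repeat mismatches, exactly 90% identity) land on the
inclusive side deterministically. All thresholds sit in `RunConfig`, whose
defaults are the published operating point (29–31; ≤1; 0.90; 2,000; 2;
20 bp/0.10; 0.98/0.95; 0.25; 5; 0.75), and a serialized copy is embedded in
every run's output directory.

## Known limitations

- The ungapped hit definition will miss protospacers containing indels;
  tools built on local alignment would recover some of these at the cost of
  a fuzzier identity definition.
- Hamming-only repeat anchoring ignores 1-edit indel variants of a
  reference repeat.
- ANI by anchor chaining assumes co-linear homology; heavily rearranged
  pairs fall back to low coverage rather than being aligned piecewise.
- Louvain communities are non-overlapping; an element genuinely shared
  between families will be assigned to exactly one.
- The ORF caller reports the longest open frame per stop and has no coding
  model, so real data would include spurious ORFs and miss genes with
  non-standard starts.
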
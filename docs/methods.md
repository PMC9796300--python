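# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data design, and the numerical and
design choices made where the problem was genuinely open.

## Assembly statistics and cleanup

**N50/L50.** Sequences are sorted by descending length; N50 is the length
of the sequence at which the cumulative sum first reaches *at least* half
the total, L50 the number of sequences up to and including it. The ≥
(rather than >) comparison means a prefix landing exactly on half
qualifies; this only matters for even totals with an exact split and is
the convention that keeps L50 minimal. Verified against brute-force
prefix enumeration on random length multisets.

**Contigs.** A scaffold is broken into contigs at N-runs of at least
`contig_gap_min` bases (default 10). Ten is also the cap applied to gaps
when building redundancy-search copies of pseudodiploid scaffolds, so
"a gap that breaks a contig" and "a gap worth capping" coincide by
default; both are flags.

**GC%.** (G+C)/(A+C+G+T) × 100. Ns and IUPAC ambiguity codes are excluded
from numerator *and* denominator, so rewriting gap lengths (see below)
cannot move GC. `gap_length` counts every N residue regardless of run
length.

**Gap standardisation.** Gaps of unknown size are rewritten to exactly
100 Ns. Which gaps are "of unknown size" is provenance the sequence
itself does not carry (it depends on how the scaffolder recorded them),
so the caller must list the runs explicitly; the operation refuses
intervals that are not entirely N. Total length changes by exactly
Σ(100 − run length) over the listed runs.

**Contaminant cleanup.** A scaffold shorter than `min_purge_len`
(default 5,000 bp) carrying any contaminant interval is removed whole.
On longer scaffolds the decision per interval follows the available
spanning-read evidence: if long reads span the region the flanking
sequence is trusted and the interval is masked to Ns in place; if not,
the junction itself is suspect and the scaffold is split at the interval
(trimmed when it touches an end). Split pieces are renamed `<id>.1`,
`<id>.2` left to right. Every action is logged with before/after ids,
coordinates and lengths; residues outside listed intervals are never
altered (checksum-tested).

## Compiled-gene completeness re-rating

Single-copy-ortholog benchmarking re-runs HMM-based gene finding per
assembly, which couples the rating to score thresholds and retrained gene
models; genes can change rating when unrelated scaffolds are added,
removed, or even reverse-complemented. The re-rating here separates
*discovery* from *rating*:

1. **Compilation.** Full tables from all runs are collated; every gene
   rated Complete (single copy) in at least one run enters the compiled
   set. The representative sequence is the Complete instance with the
   highest score, ties broken by length then by lexicographically
   smallest run id; the source run, score and length are recorded as
   provenance so the tie-break is auditable. Only the BUSCO v3 table
   dialect is parsed; v4/v5 tables are rejected with an explicit message
   rather than misread.

2. **Rating.** The compiled sequences are mapped onto each assembly (the
   aligner is out of process; the module consumes PAF). Hits below the
   local cutoff — identity (matches/block) < 0.80 or aligned query span
   < 40 bp — are discarded. The original tool's cutoff is unpublished, so
   both values are exposed as flags; the defaults are ordinary
   minimap2-era thresholds for "a real local hit". Coverage is the union
   of *query* (gene-side) intervals divided by gene length — the question
   is how much of the gene is present, not how much scaffold it occupies —
   unioned regardless of strand and computed per scaffold and overall.
   The category boundaries (95% single-scaffold for Complete/Duplicated,
   95% combined for Fragmented, 40% for Partial vs Ghost) are inclusive
   at the lower edge. Because only query intervals enter the rating, it
   is invariant under reverse-complementing target scaffolds, which is
   the robustness the method exists to provide (property-tested).

3. **Best-of compilation.** Across assemblies, each gene's best rating
   under Complete > Duplicated > Fragmented > Partial > Ghost > Missing.
   Duplicated outranks Fragmented because a duplicated gene has at least
   one full-length copy. Compiled completeness (% Complete + Duplicated)
   is monotonically non-decreasing as assemblies are added — also
   property-tested. Adding a hit can never worsen a gene's rating except
   the legitimate Complete → Duplicated transition when a second scaffold
   crosses 95%.

**Transcript mapping.** One record per transcript (primary alignment or
unmapped marker; duplicates are an error). Three disjoint counts:
unmapped, mapped with mapQ strictly below 60, and mapped at mapQ ≥ 60
(60 is the conventional "uniquely, confidently placed" score; a mapQ of
exactly 60 counts as confident).

## Annotation metric panel

Searches run in both directions between the annotated proteome and the
reference proteome; coordinates are amino-acid, 0-based half-open
internally (the m8 reader converts from 1-based inclusive). Best hits are
maximum bitscore, ties broken by minimum e-value then lexicographically
smallest target id, so results are deterministic regardless of input
order. Reciprocal best hits require agreement in both directions.

Per annotated gene with a forward hit, PROTCOV and REFCOV are the
unions of *all* HSPs between the protein and its single best reference
(split-domain alignments are common; the best HSP alone understates
coverage), and F1 is their harmonic mean 2PR/(P+R) — 0 when both are 0.
The printed form of this formula in the tool's original description has a
typographic denominator that would make the score identically 2; the
harmonic mean is the only reading consistent with "values close to 1
indicate high fidelity".

Completeness and purity are means over *all* reference proteins /
annotated genes respectively, with unhit entries contributing 0, so both
lie in [0, 100]. Purity uses each gene's PROTCOV against its best
forward hit; completeness, symmetrically, uses each reference protein's
covered fraction against its best reverse-search hit. (The original
description does not state whether unhit reference proteins enter the
completeness denominator; including them makes the score a genuine
proteome-level completeness rather than a conditional coverage, and is
the choice documented here.)

Gene-level scoring collapses the annotation to the longest isoform per
gene (ties: lexicographically smallest protein id — note this is string
order, so `p10` beats `p2`), making the homology/orthology denominators
count genes. Duplicity is genes-with-a-best-hit over distinct reference
proteins serving as some gene's best hit; compression is unique genes
that top a reference's reverse search over references with any reverse
hit; multiplicity is simply annotated genes over reference proteins.

## Pseudodiploid resolution

All-N scaffolds are removed first. For redundancy removal, scaffolds are
processed in descending size order (ties by id) and removed when the
union of their aligned intervals — restricted to hits at ≥
`identity_frac` identity — covers ≥ `containment_frac` of their
gap-capped length within an already-kept scaffold. Both thresholds
default to 1.0, the literal "100% contained / 100% identical" rule;
real aligner output rarely achieves literal 100%, so both are flags.
Mutual full containment marks the pair identical and keeps the
lexicographically smaller id. Gap capping (N-runs shortened to ≤ 10)
applies only to the search copies; emitted assemblies keep original gap
sizes.

Survivors are paired by base name (default pattern: trailing `.1`/`.2`;
any two-group regex accepted). A singleton goes to primary — its partner
was either removed as identical or never assembled (e.g. a sex-chromosome
scaffold). Of a pair, the longer goes to primary, the shorter to
alternative; exact ties resolve by id. Name-paired scaffolds with length
ratio < 0.5 are paired anyway but flagged in the decision report as
dubious haplotig pairs. Every input scaffold receives exactly one
decision (partition-tested), and primary total length ≥ alternative
total length on any input.

Depth-based haplotig classification is deliberately out of scope: this
module resolves *name-paired* pseudodiploid output, not arbitrary
redundant assemblies.

## Synthetic fixtures

The generator emulates exactly the structures the consumers measure:

* **Assemblies** — 6 scaffolds of 20–40 kb by default, residues i.i.d. at
  GC 0.42 (typical of avian genomes), 2 N-run gaps per scaffold placed in
  background sequence only. 18 genes (900–1,700 bp) cycle through the six
  intended ratings: intact on one scaffold (Complete), intact on two
  (Duplicated), two overlapping 55% pieces on different scaffolds
  (Fragmented: union 100%, no single ≥ 95%), a 60% prefix (Partial), a
  30% prefix (Ghost), or absent (Missing). Exact hits for every planted
  piece are emitted as PAF. Planted coordinates, expected ratings and a
  brute-force statistics panel form the truth.
* **Haplotig pairs** — haplotig 2 is haplotig 1 with i.i.d. substitutions
  at SNP rate 0.01 and a 5% tail truncation (both configurable to 0, in
  which case pairs are byte-identical and mutual full-containment hits
  are emitted).
* **Proteome pairs** — reference protein lengths are multiples of 4 so
  quarter-fraction truncations are exact; each reference gene yields
  `duplication_factor` annotated copies of the first `truncation_q` of
  its protein, with prefix hits in both directions; a leading
  `unhit_frac` share of genes is withheld from both hit tables. Expected
  metrics are recomputed from the constructed tables by per-base
  boolean-mask unions and naive argmax loops, sharing no code with the
  metric module.

All randomness flows from one integer seed through named per-output
streams, so adding an output kind never perturbs existing fixtures; equal
seeds give byte-identical output.

What passing these fixtures does *not* show: behaviour on repeats
(residues are i.i.d.; no transposable elements or segmental
duplications), on noisy alignments (planted hits have identity 1), on
base-calling error, or on real aligner quirks (soft-clipping, split
alignments across strands). The published-assembly statistics tests,
which download two deposited genomes, are the only checks against real
data and require network access; everything else is desk-scale by
design — the problem sizes above keep the full suite under ten seconds.

## Degenerate inputs and tie-breaks

Empty FASTA, duplicate ids, residues outside the IUPAC DNA alphabet,
empty record lists, inverted intervals, hits referencing unknown
scaffolds or genes, and >2 scaffolds sharing a haplotig base name are all
errors, reported with the offending id/position. All selection rules
(compiled representative, best hit, longest isoform, identical-pair
survivor, length-tie primary) end in a lexicographic comparison so every
result is deterministic and order-independent.
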
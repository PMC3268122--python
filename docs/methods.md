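# Methods

## The alignment engine

Every comparison in the pipeline is exact-match based. A **maximal
exact match (MEM)** between two sequences is an identical substring
pair that cannot be extended on either side; N matches nothing,
including another N. MEMs of length ≥ `min_match` (default 20 bp) are
found by k-mer seeding and extension over a sentinel-separated
concatenation of the targets, with per-diagonal deduplication so each
maximal run is extended once. Runs shadowed by a strictly longer block
in both coordinate systems (shifted boundary sub-matches, which arise
in tandem text) are suppressed, so the output equals a brute-force
enumeration of maximal common substrings; the test suite checks this
equivalence against an independent diagonal-scan oracle on randomized
instances.

MEMs are chained by sparse dynamic programming into colinear chains
(score = matched bp). Adjacent matches may be joined when the gap on
both sequences is ≤ `maxgap` (500 bp); chains with fewer than
`mincluster` (100 bp) matched bases are dropped; blocks overlapping a
higher-scoring predecessor are trimmed at their start so the
exact-match invariant survives chaining. The chain-level indel signal
is `max_indel`: the largest |query gap − target gap| over adjacent
blocks. Coordinates are 0-based half-open internally (TSV reports are
1-based inclusive); the target is always kept forward and the strand
flag describes the query.

`min_match = 20` is a choice: the seed length of this aligner family
is conventionally near 20 and the value is exposed in every config.
Containment ("identical to or a subsequence of") is tested exactly by
default, which makes consensus voting byte-deterministic; a
mismatch-tolerant mode (single chain matching ≥ a given fraction) is
available but off by default.

## Consensus selection (DBG contigs)

A contig is selected iff its length is ≥ `min_len` (500 bp, applied
before voting) and it is contained, on either strand, in contigs from
≥ `min_support` distinct assemblies. The contig's own assembly counts
(a contig trivially contains itself), so the default `min_support = 2`
demands one independent corroboration; users who read the rule as
"two assemblies besides the source" can set 3. After voting,
containment-redundant contigs are removed (descending length then id;
among identical contigs the smallest id survives).

A note on monotonicity: the *candidate* set shrinks as `min_support`
rises, but redundancy removal may then keep a contained contig whose
container only survived the looser threshold — so the guaranteed
invariant is that every contig selected at a higher threshold is
contained in some contig selected at a lower one.

## Reliability filtering of comparative contigs

Two criteria, applied to each pooled A-contig of length ≥ 500 bp:

* **No significant indels** — no assigned chain with
  `max_indel > 50` bp. The threshold quantifies "significant"; 50 bp
  cleanly separates real structural disagreement from chaining noise
  at the default `maxgap`, and is far below the 0.8–1.5 kbp events
  the simulator plants.
* **Coverage ≥ τ** — the fraction of the A-contig covered by chains
  of DBG contigs *assigned* to it must reach τ (default 0.8).

Assignment is best-hit: each DBG contig is assigned to the single
A-contig it matches best (most matched bp, then fewest indels, longer
target, lexicographic id), competed across **all** reference sets
pooled together. Counting only assigned chains is essential: a
chimeric A-contig is typically built from genuine target pieces, so
counting *all* alignments would cover it fully; under best-hit
competition the DBG contigs overlapping it prefer the genuine,
longer-matching version of the same region from another reference,
and the chimera starves below τ. This is also why at least two
references are recommended. A per-reference (non-pooled) mode exists
behind a flag for comparison only.

## Merging

Greedy overlap layout over the union of DBG contigs and reliable
A-contigs: containments are absorbed first; dovetail overlaps
(≥ `min_overlap` = 30 bp, identity ≥ 0.94, end overhangs ≤ 20 bp
trimmed) are then joined longest-overlap-first, each contig end used
at most once and cycles refused; finally any output contained in
another output is absorbed, which makes merging idempotent. Where the
two copies of an overlap disagree, the DBG copy wins (the DBG set is
the high-accuracy one). Joins between two A-contigs unsupported by
any DBG contig are permitted but tagged in the joins report. No
scaffolding is performed: only sequence-confirmed joins, never runs
of N. The identity default (0.94) follows the conventions of the
light-weight overlap assemblers this stage stands in for; exact mode
(identity 1.0) is what the deterministic tests use.

## Evaluation measures

* **complexity** — fraction of genome positions inside a non-identity
  maximal exact self-match ≥ 20 bp, both strands, positions unioned.
  Genomes worth simulating have complexity > 6e-3.
* **similarity** — (covered_a + covered_b) / (len_a + len_b) over
  MEMs ≥ 20 bp. Counting covered positions on *both* genomes (rather
  than summing match lengths once) makes identical genomes score
  exactly 1.0 and keeps the working band for reference selection at
  0.80–0.92; overlapping matches are unioned so the value never
  exceeds 1.
* **N50 (genome-relative, NG50)** — length of the first
  descending-sorted contig at which the cumulative length reaches
  half the *genome* length; 0 if it never does.
* **bona fide / accuracy** — a contig is bona fide iff its best chain
  to the truth genome matches ≥ 95% of it with `max_indel ≤ 50`;
  accuracy is the bona fide proportion. The two thresholds are this
  package's operationalisation of "maps colinearly, near full
  length".
* **rank scores** — per dataset and category (average length, N50,
  longest, genome fraction), four methods are ranked descending with
  weights 4..1 (ties share the mean weight); scores sum over
  datasets.
* **proportion extended** — fraction of de novo contigs whose
  best-hit comparative contig protrudes ≥ 10 bp past one of their
  ends, or which share a best-hit comparative contig with another de
  novo contig.

## The simulator and the standard study conditions

`simulate` generates every input the pipeline consumes, all
bit-reproducible per seed:

* **Genomes**: i.i.d. uniform background with exact planted repeat
  families at non-overlapping positions. The standard suite uses
  100-kbp genomes with families (800 bp × 3, 500 bp × 2), i.e.
  complexity ≈ 0.034 — comfortably above the 6e-3 eligibility floor.
  Genomes are linear; fragments never wrap.
* **References**: block structural events (novel-sequence insertion,
  deletion, inversion, translocation; 0.8–1.5 kbp, one per genome
  zone, logged in target coordinates) followed by point substitutions
  whose rate is bisected until exact-match similarity lands in
  0.80–0.92 — the band in which comparative assembly is useful but
  error-prone.
* **Reads**: floor(G·C/(2R)) fragments of length L at uniform starts,
  an R-bp read off each end in forward–reverse orientation; defaults
  C = 60, L = 300, R = 75; optional uniform substitution errors
  (default 0, and the validation suites run error-free). Reads carry
  a constant quality character — no quality model is attempted.
* **De novo fixture assemblies**: each assembly independently tiles
  the genome with substring contigs (lengths 0.3–1.7 × the 2-kbp
  mean, slight overlaps); with probability `chimera_rate` a contig is
  replaced by a join of two loci ≥ 10 × mean apart. Chimeras are
  drawn independently per assembly, mirroring the observation that
  different assemblers' mis-assemblies are inconsistent. Fixture
  assemblies deliberately bypass actual read assembly: the subject
  under test is the selection/filtering/merging logic, which consumes
  contigs, and planted truth labels require constructed contigs.
* **Comparative fixture contigs**: per reference, genuine contigs are
  1.5–3.5-kbp genome substrings; at each logged structural event,
  with probability `miss_rate` (1.0 in the suites) a chimeric contig
  carrying the reference's structure replaces the genuine tiling
  there, with 0.7–1.1-kbp genuine flanks around the divergence.
* **DBG tiling**: the validation suites pair the comparative sets
  with a deterministic bona fide tiling (10-kbp tiles, 4-kbp step) so
  every chimera junction is spanned with ≥ 3-kbp flanks. The
  tile/piece scale ratio follows the shape of real data — consensus
  de novo contigs are several times longer than comparative contigs
  — and that length advantage is precisely what makes best-hit
  competition decisive.

What passing the suites does and does not show: the fixtures plant
*structural* misassemblies with clean junctions and error-free contig
sequence. They exercise the selection, competition, coverage, and
merging logic end to end, but not base-level sequencing error, biased
coverage, or repeat-induced assembler behaviour — contigs are
constructed, not assembled from the simulated reads.

## Validation suites and problem sizes

`scripts/acceptance.py --seed S` runs two suites of 20 genomes each
(per-genome seeds (S−1)·20+1 … S·20):

* the comparative suite measures (t1) the pooled percentage of
  planted chimeric A-contigs excluded at τ = 0.8 (360 chimeras per
  suite), (t2) the minimum per-genome accuracy of the reliable set,
  and (t3) the minimum per-genome accuracy of the hybrid assembly;
* the consensus suite measures (t4) the minimum per-genome accuracy
  (as a percentage) of consensus-selected contigs under
  `chimera_rate = 0.1`.

The 100-kbp genome size keeps a full 20-genome suite at a few minutes
on one CPU while leaving every length scale (reads ≪ contigs ≪
events ≪ genome) in the same order as real bacterial data. The same
suites back `tests/test_acceptance.py`, together with the
oracle-equivalence suite (≥ 200 randomized trials per operation
against brute-force oracles on instances ≤ 2 kbp), threshold and
merge monotonicity checks, and the simulator contracts
(count formula, start-position uniformity, orientation,
reproducibility).

## Numerical and degenerate-input choices

* Ordering is deterministic everywhere: FASTA outputs are sorted by
  descending length then id; all tie-breaks (chain selection,
  assignment, merge order, path direction) are total orders.
* `n50` returns 0 when the assembly total never reaches half the
  genome (the boundary is otherwise undefined).
* An empty DBG set leaves every A-contig uncovered (all excluded) and
  aborts the pipeline before merging with a stage-tagged diagnostic.
* Reliability reasons are reported in the order too-short, indel,
  low-coverage (first failure wins).
* `evaluate`/verdict coverage counts assigned chains only — see
  above.

## Known limitations

* The containment test is exact by default; heavily error-laden
  contigs would need the tolerant mode and its thresholds have not
  been tuned against real data.
* The merger is a greedy path builder, not a full overlap-graph
  traversal; with highly repetitive contig ends it may prefer a
  longer spurious overlap over the true layout. Repeat-induced
  overlaps are mitigated (not eliminated) by end-anchoring.
* Scaffolding and gap filling are out of scope, as are mate-pair and
  depth-of-coverage misassembly signatures; the filter sees only
  alignment geometry.
* Circular replicons are treated as linear sequences.
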
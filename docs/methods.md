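# Methods

## Coordinates and the TTAA universe

All intervals are 0-based, half-open, in qBED output as well as internally.
*piggyBac* integrates exclusively at TTAA tetranucleotides and duplicates
the motif on insertion, so an insertion event is identified with its motif
interval `[p, p+4)`.  TTAA is its own reverse complement; the motif index is
therefore strandless, and strand on an insertion record is annotation only.
The index is built by an exhaustive single-step scan (`str.find` with
overlapping restarts); `N` never matches.  Interval queries use sorted
position arrays with binary search (`numpy.searchsorted`) — point events on
a line need nothing richer than bisection.

The unit of uniqueness for insertion events is **(chromosome, TTAA start,
barcode)**: the barcode is what distinguishes independent insertions that
landed on the same TTAA in different cells.  Collapsing sums supporting
reads into `count` and sets strand to `.` on disagreement.  Hop counting in
the peak caller uses unique events (a record with count 40 is one hop), and
exact duplicate records count once; this is what makes the caller invariant
under duplication of every input record.

## Read layout

An SRT read runs: stagger (library barcode) · TR prefix · SRT barcode ·
TR suffix · TTAA junction · genome.  The default layout is

* `tr_prefix = GTCAATTTTACGCAGACTATCTTT` (24 nt), `barcode_len = 4`,
  `tr_suffix = GG`, `junction = TTAA` — the barcoded *piggyBac* 3′-TR end
  read 5′→3′ toward the genome, with the barcode replacing the wild-type
  `CTAG` four bases from the junction;
* staggers: six sequences of lengths 1–6 (`C, GA, TGC, ACTG, GACTG,
  CGATCG`).  Only `TGC` corresponds to a published primer; the rest are
  package defaults chosen so that no stagger is a prefix of another stagger
  followed by the TR prefix, keeping stagger identification unambiguous.
  Everything is configurable; the layout is data, not code.

Parsing tolerates substitutions in the TR segments (defaults: 1 in the
prefix, 0 in the 2-nt suffix) but no indels — transposition tolerates no
change of TR length, so indel-bearing reads are junk.  Stagger matching is
exact (longest match wins).  By default the trimmed genomic fragment
**retains** the junction TTAA, anchoring alignment on the insertion site
itself; `keep_junction=False` reproduces the convention of trimming it.
Read-through adaptor (Nextera, `CTGTCTCTTATACACATCT`) is removed by exact
prefix search at its first occurrence.  Barcodes ride in read names as
`read_id_BARCODE` (the UMI-tools underscore convention), which the aligned-
read readers parse back out.

Failures are statuses, not exceptions, checked in order: stagger → TR
prefix → barcode → TR suffix → junction → fragment length; `trim_fastq`
reports counts per status.  A second fixed-position layout (16 bp sample
barcode + 10 bp UMI, the BRB-seq oligo-dT design) is handled by
`parse_tag_read` for tag extraction only.

## Insertion validation

A mapped read is a valid insertion when a TTAA start lies within ±`slack`
(default 0) of its junction-side coordinate — the aligned start for `+`
reads, the aligned end − 4 for `−` reads (a minus-strand read's junction is
its rightmost base).  The insertion takes the TTAA's own coordinates.
Reads under `min_mapq` (default 10 — multi-mappers inflate insertion
counts) or on unknown chromosomes are counted and dropped, never fatal.

## Demultiplexing and barcode codes

A manifest maps experiments to disjoint barcode sets.  Policies: `exact`
and `detect` assign members only (any non-member is a detected error);
`correct` assigns a non-member to the unique codeword within
`max_correct_distance` (default 1), leaving ties unassigned, and rewrites
the barcode to the decoded codeword.  Assignment always partitions the
input exactly.

Minimum pairwise Hamming distance ≥ 2 detects, ≥ 3 corrects, one
substitution.  `max_distance_set` builds sets at a requested distance:
greedy lexicographic first-fit (maximal, deterministic), or exact maximum
via branch-and-bound maximum-clique search on the graph joining barcodes at
distance ≥ d.  The search uses a greedy-colouring upper bound with vertices
emitted class-by-class, an incumbent seeded by the greedy code, and — when
searching the full 4^L pool — translation symmetry (position-wise alphabet
translation maps codes to codes, so A^L can be fixed as a member).  All
full-pool instances up to L = 4 solve in well under a second; correctness
is cross-checked in the tests against an independent clique solver and, for
(L=4, d=3), against the Singleton bound 4^(L−d+1) = 16, which the returned
MDS-type code attains.  The shipped `DEFAULT_DETECTING_24` is 24 length-4
barcodes at distance ≥ 2 drawn greedily from a pool excluding T at barcode
position 2 (0-based), the position where thymine strongly disfavours
transposition; it is the package's own default, not a published list.

## Abundance statistics

Barcode abundance counts **distinct collapsed insertions** per barcode.
CPM uses a 0.5 pseudocount, `CPM_i = 10^6 (n_i + 0.5) / Σ_j (n_j + 0.5)`,
so zero-count barcodes stay finite in log2; replicates combine by mean and
SEM of log2 CPM.  Per-position nucleotide frequencies weight each barcode
by its insertion count; the top-k position frequency matrix weights the k
most abundant barcodes equally (ties at rank k break lexicographically so
results are reproducible).  The species-mixing concordance rate is the
fraction of insertions whose genome of alignment matches the genome
expected for their barcode, with a per-genome breakdown.

## Peak calling

The caller follows the MACS strategy adapted to insertion counts; stages
and defaults (window 1000 bp, step 500 bp, window p 0.01, final p 0.001,
pseudocounts 0.2, λ windows 1/5/10 kb) are described in the README.
Numerical and design choices:

* **Depth scaling.** All expectations are scaled by `R = E/B` (experiment
  over background unique-hop totals).  A literal reading of the final-stage
  expectation as "λ × TTAAs × hops in peak" makes the expectation
  proportional to its own observation and is not a probability model; it
  remains available as `literal_expectation=True` for comparison.
  `depth_scale=False` disables scaling entirely.
* **Pseudocounts** act as an additive floor on expectations at both stages
  (`(b + c)·R` in the scan; `max(λ·n·R, c)` in scoring), preventing
  zero-expectation degeneracy when the local background is empty.
* **Window tiling** runs from the first to the last event position per
  chromosome (union of both frames), so output is independent of any
  declared chromosome length.
* **Center** is the lower-median experiment-hop position in the merged
  span (deterministic, always an actual hop site); midpoint when empty.
* **λ windows** with zero TTAAs are skipped; λ_bg is always available.
* **Trimming.** Reported peaks are trimmed to `[first hop, last hop + 4)`
  over the experiment hops in the merged span (`trim_to_hops=False` keeps
  the merged window span); all reported counts refer to the reported
  interval.
* The Poisson tail is the exact regularized-gamma survival function
  (`scipy.stats.poisson.sf(k−1, μ)`), with `P(X ≥ 0) = 1` and a zero-rate
  convention of 1 for k = 0, else 0.
* p-values are filtered raw at the final cutoff; a Benjamini–Hochberg
  q-value is emitted as a diagnostic column but never used for filtering.

**Calibration caveat.**  The window stage plugs the observed background
count in as if it were the known Poisson mean.  At genome-scale hop
density (well under one hop per kilobase window — e.g. 10⁴ hops spread
over tens of megabases) the scan is strongly conservative and the null
enriched-window rate sits far below the nominal cutoff, which is what the
calibration test verifies.  In artificially dense regimes (≈10 hops per
window and up) the plug-in ignores background sampling noise and the
stage becomes anti-conservative by a factor of a few; the final Poisson
stage with local λ, not the scan, is the significance statement.

## Simulator

The generator emulates the data-generating process the analysis assumes:
hops land on TTAA sites — uniformly for the background, with a
multiplicative weight (`enrichment`, default 10) on sites inside planted
peak intervals for the experiment; barcodes follow a configured
multinomial; reads are built exactly per the layout with i.i.d.
substitution errors (optionally confined to the TR segments, which makes
the parse-rate expectation a clean binomial).  Two genome modes: `grid`
(a TTAA every `ttaa_spacing` bp, default 100 — roughly the hg38 motif
density — in filler drawn from {A,C,G} so no motif arises by chance;
analytic site counts make brute-force oracles exact) and `random`
(i.i.d. bases).  Planted peaks are disjoint, evenly spaced with jitter,
and each contains at least one TTAA.

Deliberate departures from strict realism, and their consequences:

* Reads per insertion is `1 + Poisson(depth_mean − 1)`, guaranteeing every
  simulated insertion at least one read so that the zero-error round trip
  (simulate → trim → align → validate → collapse → demultiplex) reproduces
  the truth table *exactly*, which the tests assert.
* Insertions within a read length of a chromosome edge take the
  orientation whose read extends into the chromosome, so no read is
  truncated.
* No indel errors, no quality-score model (constant Q), no chimeric or
  PCR-artifact reads.  Passing tests therefore demonstrate correctness of
  the pipeline's logic under its own model, not robustness to every
  artifact of real libraries.
* Unique-event saturation is real and intended: a peak with `s` TTAA sites
  and a `k`-barcode pool holds at most `s·k` distinct events, so heavy
  simulated coverage with few barcodes flattens visible enrichment exactly
  as it would in a real low-diversity experiment.  Recovery benchmarks use
  the 24-barcode default pool, matching how barcoded SRT experiments are
  actually pooled.
* The bundled aligner is exact unique-substring placement and exists only
  so tests can run end to end; real data goes through a real aligner and
  enters via SAM/BAM or tabular aligned-read files.

Every stage derives its RNG stream from (seed, stage-salt), so outputs are
reproducible end to end and adding read simulation never perturbs the hop
draws.

## Problem sizes used in the checks

The quantitative self-checks run at desk scale, chosen to make their
statistics decisive: peak-caller/oracle agreement on a hand-computable
10 kb grid and 100 random ≤5 kb instances (tolerance 1e−10); null
calibration with 10 000 + 10 000 hops on a 500 000-site grid; planted-peak
recovery with 20 peaks at 10× enrichment and 50 000 + 50 000 hops on a
2 Mb grid; a 10 000-read zero-error round trip; Poisson tails against a
direct series on observed ≤ 50, expected ≤ 20 (tolerance 1e−12).

## Known limitations

* Demultiplexing correction assumes substitution errors only; an indel in
  the barcode shifts the junction and the read fails parsing instead.
* The exact code search is capped at 256 candidates (full pool for
  length ≤ 4); longer barcodes use greedy mode or a user-restricted pool.
* `value` in qBED output is whatever the upstream collapse produced
  (supporting reads, or molecules if deduplicated upstream); the package
  does not itself perform UMI-graph deduplication.
* Whether "unique insertion sites" should collapse across barcodes or
  across (site, barcode) pairs is application-dependent; both counts are
  available (`HopFrame.total_hops` on collapsed records vs the distinct
  site count).
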
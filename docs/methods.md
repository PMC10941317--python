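# Methods

## Setting and model

DNA-storage codecs emit fixed-length oligos over {A,C,G,T} that satisfy a
declared constraint set; sequencing returns many noisy reads per oligo.
`oligorepair` treats the constraints as a checkable code membership test:
a read that violates any rule provably contains at least one error, and the
violation's span localises it. The package's core is (i) a violation
scanner with exact spans, (ii) a per-base error metric derived from the
violations, and (iii) a greedy repair loop driven by that metric, embedded
in a cluster-level representative-selection workflow.

### Constraint rules

All coordinates are 0-based half-open. Defaults in parentheses.

* **gc_global** — overall GC fraction must lie in `[gc_min, gc_max]`
  ([0.40, 0.60]); magnitude = distance to the nearest bound.
* **gc_window** — the same bounds applied to *tiling* windows of
  `window_size` bases (15) at offsets 0, w, 2w, …; a trailing remainder
  shorter than w is evaluated as its own window. Tiling (rather than
  sliding) windows were chosen because adjacent fixed windows are what
  synthesis vendors and storage codecs typically specify; a run "between
  two GC windows" is then a meaningful event.
* **homopolymer** — no run of identical bases longer than
  `max_homopolymer` (3); one violation per maximal run of length `r > h`,
  magnitude `r − h`.
* **blacklist** — no occurrence of any listed motif (empty); overlapping
  occurrences are each reported.
* **kmer** — no k-mer of length `kmer_k` (off) may occur more than
  `kmer_max_occurrences` (1) times within one sequence. This is the
  intra-sequence repeat-avoidance constraint standard in DNA-storage code
  design; magnitude = excess occurrence count.
* **length** — sequence length must equal `target_length` (or fall in a
  (min, max) pair); magnitude = |Δ|.
* **ambiguous** — any N base always violates (an N carries no
  information and is always repair-eligible).

### Per-base error metric

`error_profile` assigns each base `e_i = Σ_r w_r · c_r(i)` with rule
weights `w_r` (default 1) and contributions designed so that editing a
high-scoring base can actually shrink the violation:

* homopolymer: every position of a violating run of length `r` scores
  `(r − h)/r` — longer runs score higher per base, and the whole run is
  eligible;
* GC (global or window): the deviation from the nearest bound, assigned
  only to *aggravating* bases — G/C when the region is too GC-rich, A/T
  when too poor — so repair never "fixes" GC by touching a base whose
  change cannot help;
* blacklist: 1 for every covered position (summed over overlapping
  occurrences);
* kmer: 1 for every position of an occurrence beyond the allowed count
  (the first `m` occurrences are treated as legitimate);
* ambiguous: 1 per N;
* length: contributes only to the signed `length_delta`, since no
  substitution can fix a length error.

With positive weights, a sequence has an all-zero profile and zero
`length_delta` exactly when it satisfies every rule; any non-length
violation necessarily puts mass on at least one base (an over-rich region
contains a G/C; an under-rich region over {A,C,G,T} contains an A/T).

### Greedy maximum-likelihood repair

Loop until valid or `max_changes` (default 8) edits spent:

1. too long (`length_delta > 0`): delete the highest-scoring base
   (ties: leftmost; all-zero profile: last base) — deleting max-error
   positions lets one edit fix a homopolymer and the length together;
2. too short: append the base minimising the resulting total error
   (ties: A<C<G<T);
3. otherwise substitute, at the highest-scoring position, the alternative
   base minimising the resulting total error, accepted only on a *strict*
   decrease; if no base helps, the next-highest position is tried; if none
   helps, the repair fails ("stuck") rather than looping.

Every tie-break is fixed (leftmost position, A<C<G<T), so identical inputs
give identical edit lists. Termination is guaranteed: indel steps strictly
shrink |Δ| and substitution steps strictly shrink the total error. The
loop is a heuristic: it can fail on inputs a brute-force search could fix,
which is why the test suite asserts only one-sided agreement with an
exhaustive ≤ k-edit enumeration (every greedy success is confirmed; greedy
failures are allowed). Successful outputs are *valid*, not necessarily the
originating oligo — see Limitations.

### Cluster workflow

Members are sorted by (edit distance to centroid ascending, abundance
descending, id ascending); edit distances are Levenshtein with unit costs
(computed with edlib). If the centroid is violation-free the cluster is
`correct`; else the first violation-free member in the sort order replaces
it (`substituted`); else members are repaired — all of them by default
(`exhaustive`), keeping the success with the fewest changes, or stopping at
the first success when configured — and clusters with no repairable member
are `unrecoverable` and excluded from output. With `keep_original`, both
the original centroid (tagged `original`) and the representative (tagged
`repaired:k`) are emitted. Each processed cluster contributes one entry to
the JSON repair report (schema shipped as `report_schema.json`).

### Clustering, dereplication, filtering

Dereplication collapses identical strings, summing abundance and taking
id/qualities from the highest-mean-quality member. Greedy clustering sorts
the pool by abundance (or mean quality), ties by id, pops the head as
centroid and sweeps in every sequence with similarity strictly above the
threshold (default 0.97), where similarity = `1 − d_Lev/max(len)` — an
alignment-free surrogate for alignment identity that is monotone in edit
distance. Quality filtering removes reads whose arithmetic-mean PHRED is
*below* the threshold (default 10; reads exactly at it are kept).
Demultiplexing uses exact barcode prefixes, longest match first; primer
trimming allows a Hamming-mismatch budget and routes unmatched reads to a
reject stream. Constraint handling runs in *filter* mode (drop violating
reads) or *sort* mode, which orders reads ascending by
`penalty − λ · meanQ/93` (λ default 1), where penalty is the weighted
violation count — a linear combination chosen so that a rateless decoder
reads clean, high-quality sequences first while nothing is discarded.

### Pipeline

Fixed stage order: demultiplex → quality filter → trim → dereplicate →
constraint filter/sort → cluster → repair. Repair operates on clusters, so
requesting it without clustering is a configuration error raised before any
I/O. Unknown config keys are rejected; all defaults are materialised and
echoed to `resolved_config.yaml` in the output directory.

## Synthetic channel

The simulator emulates what a storage experiment hands the pipeline:

* references built base-by-base with rng-shuffled candidates, pruning
  (run length, motif suffixes, k-mer counts, GC feasibility of the open
  window and of the whole sequence) and backtracking; every emitted
  reference passes the full rule check;
* per-reference read counts `round(coverage · LogNormal(0, σ))` with
  σ = 0.5 by default, a log-normal skew standing in for PCR amplification
  bias;
* per base: deletion with `del_rate` (0.005), else substitution to a
  uniform other base with `sub_rate` (0.01), insertion after each base
  with `ins_rate` (0.005); defaults sized so a 60 nt read carries ~1.2
  errors, enough to exercise every repair path;
* a two-level quality model: correct bases draw PHRED around
  `q_correct` = 35, erroneous ones around `q_error` = 12 (SD 3, truncated
  to [2, 41]) — sufficient to exercise mean-quality filtering and
  quality-ordered clustering, but deliberately not a position- or
  motif-dependent error model;
* a ground-truth table of injected edits per read that replays exactly,
  and byte-identical outputs for equal seeds.

What it does **not** emulate: position-dependent Illumina error profiles,
motif-dependent synthesis errors, nanopore homopolymer-length miscalls,
chimeras, or adapter read-through. Tests that pass on this channel
therefore demonstrate the pipeline's logic and bookkeeping, not its
performance on any particular instrument.

## Problem sizes used in the bundled experiments

The repair soundness suite runs 1,000 channel-corrupted 60 nt reads; the
brute-force detection oracle 1,000 random sequences up to 200 nt; the
greedy-vs-enumeration oracle 500 sequences of 8–12 nt with an edit budget
of 2; the end-to-end recovery experiment 50 references × 60 nt at mean
coverage 20 (1 % substitutions, 0.5 % insertions and deletions) over ten
seeds, plus a coverage scan from 4 to 30. These sizes keep the whole suite
in the minutes range on one CPU while leaving each check statistically
meaningful.

## Known limitations

* **Repair restores validity, not identity.** The error metric measures
  distance-to-the-code, not distance-to-the-transmitted-oligo; a repaired
  sequence is guaranteed rule-conformant but only coincides with the
  original oligo when the code leaves a single plausible fix (as in the
  window-straddling run example). In the end-to-end recovery experiment,
  a reference none of whose reads is error-free can therefore not, in
  general, be reconstructed *string-exactly*: an interior deletion, for
  instance, is repaired by an end-insertion that fixes length and GC but
  not the original base ordering. Recovery measured by exact string
  equality consequently under-states what a downstream error-correcting
  decoder (which tolerates near-miss sequences) would achieve, and the
  bundled recovery check at 60 nt reflects exactly this gap.
* **Threshold granularity at short lengths.** At 60 nt, a 0.97 similarity
  threshold admits only distance-1 members, fragmenting a reference's
  2-error reads into singleton clusters; the threshold should be set from
  the code's minimum distance and the oligo length, which the default does
  not know.
* **Abundance ties.** When several distinct reads share an abundance, the
  id-based tie-break makes the centroid choice arbitrary among them; a
  valid-but-erroneous read can then be tagged `correct` and shadow an
  error-free read in the same cluster. Deeper coverage (which breaks ties
  through dereplication) is the practical remedy.
* The greedy loop places insertions only at the sequence end, and breaks
  score ties positionally; both are deterministic simplifications, not
  optimality claims.
* Similarity is Levenshtein-based, not terminal-gap-aware alignment
  identity; boundary cases may cluster differently than alignment-based
  tools.
* Paired-end merging, host-genome separation and assembly are out of
  scope; inputs are single-end or pre-merged reads.
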
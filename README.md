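# oligorepair

Constraint-aware processing of raw sequencing reads for DNA data storage.

Storage codecs translate binary data into pools of short synthetic DNA
sequences (oligos) that must satisfy hard design constraints: GC content
bounded in 40–60 % globally and per window, homopolymer runs of limited
length, no forbidden motifs, limited k-mer repetition, and a fixed codeword
length. Because *every* encoded oligo satisfies these rules, a rule
violation observed in a sequencing read is direct evidence of a synthesis,
PCR or sequencing error — and the location of the violation points at the
suspect bases. `oligorepair` uses that prior information while turning raw
FASTQ reads back into candidate codewords, for people running DNA-storage
experiments who need to recover encoded data from noisy reads.

The package provides, as a library and a CLI:

* **Constraint checking** — `find_violations` reports every rule breach
  with an exact span, and `error_profile` converts breaches into a
  per-base error score `e_i = Σ_r w_r · c_r(i)` (rule weight `w_r`, rule
  contribution `c_r`, e.g. `(r−h)/r` for every base of a homopolymer run of
  length `r` against a bound `h`).
* **Maximum-likelihood repair** — a greedy loop that edits the base with
  the highest error score so as to minimise the total error of the
  sequence: deletions while the read is too long, end-insertions while too
  short, otherwise the substitution that most reduces the total error; it
  stops after a user-defined number of changes `n` and reports the ordered
  edit list.
* **Cluster-level selection/repair** — keep a violation-free centroid,
  else promote the nearest violation-free member, else repair members and
  keep the success with the fewest changes (clusters are tagged
  `correct` / `substituted` / `repaired` / `unrecoverable`).
* **Read processing** — mean-PHRED quality filtering (`Q = −10·log₁₀ Pe`),
  barcode demultiplexing, primer/barcode trimming by sequence or length,
  dereplication with `;size=N` abundance annotation, greedy centroid
  clustering by similarity `1 − d_Lev(a,b)/max(|a|,|b|)` with a default
  threshold of 0.97, and two constraint-handling modes: *filter*
  (drop violating reads) and *sort* (reorder by weighted violations minus
  scaled mean quality, dropping nothing — for rateless decoders).
* **A channel simulator** — constraint-satisfying reference oligos,
  log-normal abundance skew, per-base substitution/indel errors with
  PHRED-annotated reads and a ground-truth edit table, fully reproducible
  from a seed.

## Worked example

A 32 nt read contains a single run of five A's, its GC content is within
bounds globally and in every 15-base window, and the code demands length 30
with homopolymer runs of at most 3:

```python
from oligorepair import ConstraintSet, find_violations, repair_sequence

cs = ConstraintSet(target_length=30)   # GC [0.40, 0.60], 15 nt windows, runs <= 3
read = "CGTCGAAAAACTGCTGTCAGTCAGTCAGTCAG"

for v in find_violations(read, cs):
    print(v.rule, v.span, v.magnitude)
result = repair_sequence(read, cs)
print(result.success, result.n_changes)
print(result.repaired)
```

prints

```
homopolymer (5, 10) 2
length (0, 32) 2
True 3
CGTCGCAAACTGCTGTCAGTCAGTCAGTCA
```

The checker flags the five run positions and the two-base length excess;
the repair deletes two maximum-error bases and breaks the remaining run
with one substitution, leaving a 30 nt sequence whose longest run is 3 and
which passes every rule. The same scenario from the shell:

```sh
oligorepair simulate --seed 7 --out simdata        # references + noisy reads
oligorepair pipeline simdata/reads.fastq --config pipeline.yaml --out results
```

`results/` then holds `representatives.fasta` (one representative per
cluster, with abundance and repair tags), `report.json` (per-cluster repair
outcomes and edit lists), `counts.tsv` (per-stage read accounting) and
`resolved_config.yaml` (every default materialised, so the run is
reproducible from its outputs alone).

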
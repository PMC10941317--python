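"""Synthetic DNA-storage channel: reference oligos plus noisy reads.

Emulates what a storage experiment hands the read-processing pipeline:

* a pool of *constraint-satisfying* reference oligos (stand-ins for encoded
  codewords), built base-by-base with backtracking so every reference
  passes :func:`~oligorepair.constraints.find_violations`;
* per-reference read counts with log-normal abundance skew (PCR
  amplification bias);
* per-read substitution/insertion/deletion errors with a two-level quality
  model (high PHRED around correct bases, low around erroneous ones).

Every stochastic choice flows through one seeded ``numpy`` generator, so a
dataset is byte-reproducible from its seed, and each read carries its
ground-truth edit list for truth-based assertions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .constraints import ConstraintSet, find_violations
from .io import SequenceRecord, write_fasta, write_fastq

BASES = "ACGT"

_QUAL_SD = 3.0
_QUAL_LO, _QUAL_HI = 2, 41  # Illumina-style quality range


@dataclass
class ChannelParams:
    """Sequencing-channel model parameters.

    ``coverage`` is the mean reads per reference; ``abundance_dispersion``
    the sigma of the log-normal per-reference count multiplier (0 = uniform
    coverage).  Error rates are per reference base (``ins_rate`` applies
    after each base).  ``q_correct``/``q_error`` are the mean PHRED scores
    drawn around correct and erroneous bases.
    """

    n_refs: int = 50
    ref_length: int = 60
    coverage: float = 20.0
    abundance_dispersion: float = 0.5
    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    q_correct: float = 35.0
    q_error: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_refs < 1:
            raise ValueError("n_refs must be >= 1")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")


class GenerationError(RuntimeError):
    """Reference generation exhausted its backtracking budget."""


def generate_reference(
    cs: ConstraintSet,
    length: int,
    rng: np.random.Generator,
    max_steps: int = 200_000,
) -> str:
    """One random constraint-satisfying sequence of the given length.

    Depth-first construction with rng-shuffled candidate bases; prunes
    prefixes whose current GC window or homopolymer run can no longer lead
    to a valid completion, and backtracks on dead ends.  Raises
    :class:`GenerationError` naming the most-binding rule if the step
    budget runs out.
    """
    w = cs.window_size
    prune_counts: dict[str, int] = {}
    steps = 0

    prefix: list[str] = []
    # stack of candidate lists still untried at each depth
    stack: list[list[str]] = [_shuffled(rng)]
    while stack:
        steps += 1
        if steps > max_steps:
            binding = max(prune_counts, key=prune_counts.get) if prune_counts else "length"
            raise GenerationError(
                f"no valid sequence of length {length} found in {max_steps} steps; "
                f"most binding rule: {binding}"
            )
        candidates = stack[-1]
        if not candidates:
            stack.pop()
            if prefix:
                prefix.pop()
            continue
        base = candidates.pop()
        reason = _prune_reason(prefix, base, cs, length)
        if reason is not None:
            prune_counts[reason] = prune_counts.get(reason, 0) + 1
            continue
        prefix.append(base)
        if len(prefix) == length:
            seq = "".join(prefix)
            if not find_violations(seq, cs):
                return seq
            prune_counts["final_check"] = prune_counts.get("final_check", 0) + 1
            prefix.pop()
            continue
        stack.append(_shuffled(rng))
    binding = max(prune_counts, key=prune_counts.get) if prune_counts else "length"
    raise GenerationError(
        f"constraint set unsatisfiable at length {length}; most binding rule: {binding}"
    )


def _shuffled(rng: np.random.Generator) -> list[str]:
    order = list(BASES)
    rng.shuffle(order)
    return order


def _prune_reason(
    prefix: list[str], base: str, cs: ConstraintSet, length: int
) -> Optional[str]:
    """Why ``prefix + base`` cannot extend to a valid sequence (None if it can)."""
    pos = len(prefix)

    run = 1
    i = pos - 1
    while i >= 0 and prefix[i] == base:
        run += 1
        i -= 1
    if run > cs.max_homopolymer:
        return "homopolymer"

    if cs.blacklist:
        tail = "".join(prefix[-(max(map(len, cs.blacklist)) - 1) :]) + base
        for motif in cs.blacklist:
            if tail.endswith(motif):
                return "blacklist"

    if cs.kmer_k is not None and pos + 1 >= cs.kmer_k:
        text = "".join(prefix) + base
        kmer = text[-cs.kmer_k :]
        if _count_overlapping(text, kmer) > cs.kmer_max_occurrences:
            return "kmer"

    # GC feasibility of the window the new base falls in
    w = cs.window_size
    ws = (pos // w) * w
    w_full = min(w, length - ws)
    gc_in_window = sum(1 for b in prefix[ws:] if b in "GC") + (1 if base in "GC" else 0)
    filled = pos - ws + 1
    remaining = w_full - filled
    if gc_in_window > cs.gc_window_max * w_full + 1e-9:
        return "gc_window"
    if gc_in_window + remaining < cs.gc_window_min * w_full - 1e-9:
        return "gc_window"

    gc_total = sum(1 for b in prefix if b in "GC") + (1 if base in "GC" else 0)
    rest = length - pos - 1
    if gc_total > cs.gc_max * length + 1e-9:
        return "gc_global"
    if gc_total + rest < cs.gc_min * length - 1e-9:
        return "gc_global"
    return None


def _count_overlapping(text: str, sub: str) -> int:
    count, start = 0, 0
    while True:
        idx = text.find(sub, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


# ---------------------------------------------------------------------------
# Error channel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelEdit:
    """One injected error, anchored on the reference coordinate system.

    ``ins`` places ``base`` after reference position ``ref_pos``.
    """

    op: str  # sub | del | ins
    ref_pos: int
    base: Optional[str] = None

    def __str__(self) -> str:
        return f"{self.op}@{self.ref_pos}" + (f":{self.base}" if self.base else "")

    @classmethod
    def parse(cls, text: str) -> "ChannelEdit":
        head, _, base = text.partition(":")
        op, _, pos = head.partition("@")
        return cls(op=op, ref_pos=int(pos), base=base or None)


def apply_channel_edits(reference: str, edits: list[ChannelEdit]) -> str:
    """Replay an injected edit list against its reference."""
    by_pos: dict[int, list[ChannelEdit]] = {}
    for e in edits:
        by_pos.setdefault(e.ref_pos, []).append(e)
    out: list[str] = []
    for i, b in enumerate(reference):
        here = by_pos.get(i, [])
        sub = next((e for e in here if e.op == "sub"), None)
        dele = next((e for e in here if e.op == "del"), None)
        if dele is None:
            out.append(sub.base if sub else b)
        for e in here:
            if e.op == "ins":
                out.append(e.base)
    return "".join(out)


@dataclass
class CorruptedRead:
    record: SequenceRecord
    ref_id: str
    edits: list[ChannelEdit]


def corrupt(
    reference: str,
    params: ChannelParams,
    rng: np.random.Generator,
    read_id: str = "read",
    ref_id: str = "ref",
) -> CorruptedRead:
    """Push one reference through the error channel.

    Per reference base: deletion with probability ``del_rate``, otherwise
    substitution to a uniformly random *other* base with ``sub_rate``; after
    each base an insertion of a uniform base with ``ins_rate``.  Correct
    bases draw qualities around ``q_correct``, erroneous ones around
    ``q_error`` (both truncated to [2, 41]).
    """
    bases: list[str] = []
    erroneous: list[bool] = []
    edits: list[ChannelEdit] = []
    for i, b in enumerate(reference):
        if rng.random() < params.del_rate:
            edits.append(ChannelEdit("del", i))
        elif rng.random() < params.sub_rate:
            new = BASES.replace(b, "")[rng.integers(3)]
            edits.append(ChannelEdit("sub", i, new))
            bases.append(new)
            erroneous.append(True)
        else:
            bases.append(b)
            erroneous.append(False)
        if rng.random() < params.ins_rate:
            ins = BASES[rng.integers(4)]
            edits.append(ChannelEdit("ins", i, ins))
            bases.append(ins)
            erroneous.append(True)
    quals = [
        _draw_qual(rng, params.q_error if err else params.q_correct)
        for err in erroneous
    ]
    record = SequenceRecord(id=read_id, bases="".join(bases), quals=quals)
    return CorruptedRead(record=record, ref_id=ref_id, edits=edits)


def _draw_qual(rng: np.random.Generator, mean: float) -> int:
    return int(np.clip(round(rng.normal(mean, _QUAL_SD)), _QUAL_LO, _QUAL_HI))


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    references: list[SequenceRecord]
    reads: list[SequenceRecord]
    truth: list[CorruptedRead] = field(repr=False, default_factory=list)

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.fasta",
            "reads": outdir / "reads.fastq",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.references, paths["references"])
        write_fastq(self.reads, paths["reads"])
        with paths["truth"].open("w", newline="") as out:
            writer = csv.writer(out, delimiter="\t", lineterminator="\n")
            writer.writerow(["read_id", "ref_id", "n_edits", "edit_list"])
            for cr in self.truth:
                writer.writerow(
                    [cr.record.id, cr.ref_id, len(cr.edits),
                     ";".join(str(e) for e in cr.edits)]
                )
        return paths


def simulate_dataset(
    cs: ConstraintSet,
    params: ChannelParams,
    outdir: Optional[Union[str, Path]] = None,
) -> SimulatedDataset:
    """References + noisy reads + truth table, reproducible from the seed.

    Per-reference read counts are ``round(coverage * LogNormal(0, sigma))``
    (dispersion 0 gives exactly ``round(coverage)`` reads each).
    """
    if cs.length_delta(params.ref_length) != 0:
        raise ValueError(
            f"ref_length {params.ref_length} conflicts with the constraint set's "
            f"length rule {cs.target_length}"
        )
    rng = np.random.default_rng(params.seed)
    references = [
        SequenceRecord(id=f"ref{i:04d}",
                       bases=generate_reference(cs, params.ref_length, rng))
        for i in range(params.n_refs)
    ]
    counts = [
        max(0, round(params.coverage * float(rng.lognormal(0.0, params.abundance_dispersion))))
        if params.abundance_dispersion > 0
        else round(params.coverage)
        for _ in references
    ]
    reads: list[SequenceRecord] = []
    truth: list[CorruptedRead] = []
    read_idx = 0
    for ref, count in zip(references, counts):
        for _ in range(count):
            cr = corrupt(ref.bases, params, rng,
                         read_id=f"read{read_idx:06d}", ref_id=ref.id)
            reads.append(cr.record)
            truth.append(cr)
            read_idx += 1
    dataset = SimulatedDataset(references=references, reads=reads, truth=truth)
    if outdir is not None:
        dataset.write(outdir)
    return dataset
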
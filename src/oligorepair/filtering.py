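"""Read filtering: mean-quality, demultiplexing, trimming, and the two
constraint-violation handling modes.

Constraint handling offers two modes.  *Filter* mode drops every read with
at least one rule violation, guaranteeing downstream decoders see only
valid codewords.  *Sort* mode drops nothing: reads are reordered by a
combined key — weighted violation count minus a scaled mean quality — so a
rateless (fountain-code) decoder consumes clean, high-quality sequences
first and only reaches rule-violating, low-quality ones if it still needs
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .constraints import ConstraintSet, find_violations, violation_penalty
from .io import PHRED_MAX, PrimerRow, PrimerTable, SequenceRecord

UNDETERMINED = "undetermined"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class FilterParams:
    """Quality/constraint filtering knobs.

    ``min_mean_q`` is the mean-PHRED threshold (reads exactly at it are
    kept); ``mode`` selects between dropping violating reads ("filter") and
    penalty-sorting them ("sort"); ``quality_weight`` is the λ ≥ 0 scaling
    of normalised mean quality in the sort key.
    """

    min_mean_q: float = 10.0
    mode: str = "filter"
    quality_weight: float = 1.0
    rule_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.min_mean_q <= PHRED_MAX):
            raise ValueError(f"min_mean_q must be in [0, {PHRED_MAX}]")
        if self.mode not in ("filter", "sort"):
            raise ValueError("mode must be 'filter' or 'sort'")
        if self.quality_weight < 0:
            raise ValueError("quality_weight must be >= 0")


def mean_phred(record: SequenceRecord) -> float:
    """Arithmetic mean of the per-base PHRED integers."""
    q = record.mean_quality()
    if q is None:
        raise ValueError(f"record {record.id!r} has no quality scores")
    return q


def quality_filter(
    records: Iterable[SequenceRecord], min_mean_q: float
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition reads into (kept, removed) by mean PHRED quality.

    Reads *below* the threshold are removed; reads exactly at it are kept.
    """
    kept, removed = [], []
    for rec in records:
        (kept if mean_phred(rec) >= min_mean_q else removed).append(rec)
    return kept, removed


def demultiplex(
    records: Iterable[SequenceRecord], table: PrimerTable
) -> dict[str, list[SequenceRecord]]:
    """Assign reads to samples by exact barcode prefix (longest match wins).

    Reads matching no barcode land in the ``"undetermined"`` bin.  Nothing
    is trimmed here — see :func:`trim_extras`.
    """
    barcodes = table.barcodes()  # raises on shared barcodes
    by_length = sorted(barcodes, key=len, reverse=True)
    bins: dict[str, list[SequenceRecord]] = {name: [] for name in table.rows}
    bins[UNDETERMINED] = []
    for rec in records:
        for bc in by_length:
            if rec.bases.startswith(bc):
                bins[barcodes[bc]].append(rec)
                break
        else:
            bins[UNDETERMINED].append(rec)
    return bins


def _hamming_match(bases: str, motif: str, offset: int, mismatches: int) -> bool:
    if offset + len(motif) > len(bases):
        return False
    budget = mismatches
    for a, b in zip(bases[offset : offset + len(motif)], motif):
        if a != b:
            budget -= 1
            if budget < 0:
                return False
    return True


class PrimerNotFound(ValueError):
    """A configured primer/barcode was not found within the mismatch budget."""


def _cut(rec: SequenceRecord, start: int, end: Optional[int] = None) -> SequenceRecord:
    end = len(rec.bases) if end is None else end
    return replace(
        rec,
        bases=rec.bases[start:end],
        quals=rec.quals[start:end] if rec.quals is not None else None,
    )


def trim_extras(rec: SequenceRecord, row: PrimerRow, mismatches: int = 0) -> SequenceRecord:
    """Strip barcode/primers per the sample's primer-table row.

    The 5' end loses the barcode, then the forward primer (exact or within
    ``mismatches`` Hamming errors); the 3' end loses the reverse-complemented
    reverse primer.  A trim *length* removes that many bases unconditionally.
    Qualities are trimmed in lockstep.  A configured primer that cannot be
    matched raises :class:`PrimerNotFound` so the caller can route the read
    to a reject stream.
    """
    out = rec
    if row.barcode:
        if not _hamming_match(out.bases, row.barcode, 0, mismatches):
            raise PrimerNotFound(f"{rec.id}: barcode {row.barcode} not at 5' end")
        out = _cut(out, len(row.barcode))
    if row.fprimer_len is not None:
        out = _cut(out, min(row.fprimer_len, len(out.bases)))
    elif row.fprimer:
        if not _hamming_match(out.bases, row.fprimer, 0, mismatches):
            raise PrimerNotFound(f"{rec.id}: forward primer {row.fprimer} not at 5' end")
        out = _cut(out, len(row.fprimer))
    if row.rprimer_len is not None:
        out = _cut(out, 0, max(0, len(out.bases) - row.rprimer_len))
    elif row.rprimer:
        tail = reverse_complement(row.rprimer)
        offset = len(out.bases) - len(tail)
        if offset < 0 or not _hamming_match(out.bases, tail, offset, mismatches):
            raise PrimerNotFound(f"{rec.id}: reverse primer {row.rprimer} not at 3' end")
        out = _cut(out, 0, offset)
    return out


def trim_all(
    records: Iterable[SequenceRecord], row: PrimerRow, mismatches: int = 0
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Apply :func:`trim_extras` to a stream; returns (trimmed, rejected)."""
    trimmed, rejected = [], []
    for rec in records:
        try:
            trimmed.append(trim_extras(rec, row, mismatches))
        except PrimerNotFound:
            rejected.append(replace(rec, tags=rec.tags | {"reject:primer"}))
    return trimmed, rejected


def constraint_filter(
    records: Iterable[SequenceRecord], cs: ConstraintSet
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition into (violation-free, violating); removal reasons are tagged."""
    kept, removed = [], []
    for rec in records:
        violations = find_violations(rec.bases, cs)
        if violations:
            reasons = sorted({v.rule for v in violations})
            removed.append(replace(rec, tags=rec.tags | {f"reject:{r}" for r in reasons}))
        else:
            kept.append(rec)
    return kept, removed


def constraint_sort(
    records: Iterable[SequenceRecord],
    cs: ConstraintSet,
    quality_weight: float = 1.0,
) -> list[SequenceRecord]:
    """Reorder (never drop) reads so decoders meet the best ones first.

    Ascending by ``penalty - λ * mean_q / 93`` (records without qualities
    count mean quality 0), ties by abundance descending then id ascending.
    The output is a permutation of the input.
    """

    def key(rec: SequenceRecord):
        q = rec.mean_quality() or 0.0
        return (
            violation_penalty(rec.bases, cs) - quality_weight * q / PHRED_MAX,
            -rec.abundance,
            rec.id,
        )

    return sorted(records, key=key)
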
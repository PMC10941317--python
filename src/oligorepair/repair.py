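"""Maximum-likelihood repair of constraint-violating reads.

A read that breaches the storage code's constraints must contain at least
one error.  The repair loop greedily edits the bases most implicated by the
per-base error metric (:func:`~oligorepair.constraints.error_profile`) until
the sequence satisfies every rule or an edit budget is exhausted:

1. If the read is too long, delete the highest-scoring base.
2. If too short, append the base that minimises the resulting total error.
3. Otherwise substitute, at the highest-scoring position, the alternative
   base that minimises the resulting total error — accepted only if it
   *strictly* reduces it (otherwise the next-highest position is tried;
   if no single substitution helps, the repair fails).

All ties break deterministically (leftmost position, base order A<C<G<T), so
identical inputs always yield identical edits.  The procedure is greedy and
may fail on sequences a brute-force search could fix; in practice a read
within a few errors of a valid codeword is recovered.

The cluster-level workflow mirrors how a storage pipeline consumes clusters
of dereplicated reads: keep a violation-free centroid ("correct"), else
promote a violation-free member ("substituted"), else repair members and
keep the cheapest success ("repaired"), else drop the cluster
("unrecoverable").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import edlib

from .constraints import ConstraintSet, error_profile, find_violations
from .io import SequenceRecord

BASES = "ACGT"  # candidate order is the tie-break order
DEFAULT_MAX_CHANGES = 8


@dataclass(frozen=True)
class Edit:
    """One repair edit.  ``position`` is a 0-based index on the sequence the
    edit is applied to; an insertion places ``to_base`` before that index."""

    op: str  # substitution | deletion | insertion
    position: int
    from_base: Optional[str] = None
    to_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.op == "substitution":
            assert self.from_base and self.to_base and self.from_base != self.to_base
        elif self.op == "deletion":
            assert self.from_base and self.to_base is None
        elif self.op == "insertion":
            assert self.to_base and self.from_base is None
        else:
            raise ValueError(f"unknown edit op {self.op!r}")

    def apply(self, bases: str) -> str:
        if self.op == "substitution":
            assert bases[self.position] == self.from_base
            return bases[: self.position] + self.to_base + bases[self.position + 1 :]
        if self.op == "deletion":
            assert bases[self.position] == self.from_base
            return bases[: self.position] + bases[self.position + 1 :]
        return bases[: self.position] + self.to_base + bases[self.position :]

    def to_dict(self) -> dict:
        return {"op": self.op, "position": self.position,
                "from_base": self.from_base, "to_base": self.to_base}


@dataclass
class RepairResult:
    repaired: str
    edits: list[Edit]
    success: bool

    @property
    def n_changes(self) -> int:
        return len(self.edits)


@dataclass
class Cluster:
    """A centroid plus its members, annotated after repair with a status and
    the chosen representative."""

    centroid: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)
    status: Optional[str] = None  # correct | substituted | repaired | unrecoverable
    chosen: Optional[SequenceRecord] = None
    edits: list[Edit] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.centroid.id

    def all_records(self) -> list[SequenceRecord]:
        return [self.centroid] + [m for m in self.members if m is not self.centroid]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit substitution/insertion/deletion costs)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def repair_sequence(
    bases: str, cs: ConstraintSet, max_changes: int = DEFAULT_MAX_CHANGES
) -> RepairResult:
    """Greedy error-metric-guided repair of one sequence.

    Returns a :class:`RepairResult`; ``success=False`` (never an exception)
    when the edit budget runs out or no single edit strictly reduces the
    error.  On success the repaired sequence passes ``find_violations``
    with an empty list and the edit list replays the input into the output.
    """
    if max_changes < 0:
        raise ValueError("max_changes must be >= 0")
    current = bases
    edits: list[Edit] = []
    while True:
        if not find_violations(current, cs):
            return RepairResult(repaired=current, edits=edits, success=True)
        if len(edits) >= max_changes:
            return RepairResult(repaired=current, edits=edits, success=False)
        profile = error_profile(current, cs)
        if profile.length_delta > 0:
            edit = _best_deletion(current, profile.scores)
        elif profile.length_delta < 0:
            edit = _best_end_insertion(current, cs)
        else:
            edit = _best_substitution(current, cs, profile)
            if edit is None:  # stuck: no single substitution strictly helps
                return RepairResult(repaired=current, edits=edits, success=False)
        current = edit.apply(current)
        edits.append(edit)


def _best_deletion(bases: str, scores: list[float]) -> Edit:
    # highest error score, leftmost on ties; all-zero profile -> trim the end
    if any(scores):
        pos = max(range(len(bases)), key=lambda i: (scores[i], -i))
    else:
        pos = len(bases) - 1
    return Edit("deletion", pos, from_base=bases[pos])


def _best_end_insertion(bases: str, cs: ConstraintSet) -> Edit:
    best_base = min(BASES, key=lambda b: error_profile(bases + b, cs).total)
    return Edit("insertion", len(bases), to_base=best_base)


def _best_substitution(
    bases: str, cs: ConstraintSet, profile
) -> Optional[Edit]:
    current_total = profile.total
    # positions in decreasing score order, leftmost first on ties
    candidates = sorted(
        (i for i in range(len(bases)) if profile.scores[i] > 0),
        key=lambda i: (-profile.scores[i], i),
    )
    for pos in candidates:
        best: Optional[tuple[float, str]] = None
        for b in BASES:
            if b == bases[pos]:
                continue
            total = error_profile(bases[:pos] + b + bases[pos + 1 :], cs).total
            if best is None or total < best[0]:
                best = (total, b)
        if best is not None and best[0] < current_total:
            return Edit("substitution", pos, from_base=bases[pos], to_base=best[1])
    return None


def sort_members(members: list[SequenceRecord], centroid: SequenceRecord) -> list[SequenceRecord]:
    """Cluster members by (edit distance to centroid asc, abundance desc, id asc)."""
    return sorted(
        members,
        key=lambda m: (edit_distance(m.bases, centroid.bases), -m.abundance, m.id),
    )


def repair_cluster(
    cluster: Cluster,
    cs: ConstraintSet,
    max_changes: int = DEFAULT_MAX_CHANGES,
    exhaustive: bool = True,
) -> Cluster:
    """Choose or repair a cluster's representative.

    The centroid is kept if violation-free; otherwise the first violation-free
    member (sorted by edit distance to the centroid) replaces it; otherwise
    members are repaired — all of them when ``exhaustive`` (default), keeping
    the success with the fewest changes, or stopping at the first success.
    Clusters where every repair fails are flagged unrecoverable.
    """
    if cluster.centroid is None:
        raise ValueError("cannot repair an empty cluster")
    records = cluster.all_records()

    if not find_violations(cluster.centroid.bases, cs):
        chosen = replace(cluster.centroid, tags=cluster.centroid.tags | {"correct"})
        return replace(cluster, status="correct", chosen=chosen, edits=[])

    ordered = sort_members(records, cluster.centroid)
    for rec in ordered:
        if not find_violations(rec.bases, cs):
            chosen = replace(rec, tags=rec.tags | {"substituted"})
            return replace(cluster, status="substituted", chosen=chosen, edits=[])

    best: Optional[tuple[int, int, SequenceRecord, RepairResult]] = None
    for order_idx, rec in enumerate(ordered):
        result = repair_sequence(rec.bases, cs, max_changes=max_changes)
        if not result.success:
            continue
        if not exhaustive:
            best = (result.n_changes, order_idx, rec, result)
            break
        if best is None or (result.n_changes, order_idx) < (best[0], best[1]):
            best = (result.n_changes, order_idx, rec, result)

    if best is None:
        return replace(cluster, status="unrecoverable", chosen=None, edits=[])

    n_changes, _, source, result = best
    chosen = replace(
        source,
        bases=result.repaired,
        quals=None,  # qualities no longer describe the edited bases
        tags=source.tags | {f"repaired:{n_changes}"},
    )
    return replace(cluster, status="repaired", chosen=chosen, edits=list(result.edits))


def keep_original_option(cluster: Cluster, keep_original: bool) -> Iterator[SequenceRecord]:
    """Emit a repaired cluster's output records.

    With ``keep_original`` set, a repaired or substituted cluster emits both
    the original centroid (tagged ``"original"``) and the representative;
    otherwise only the representative.  Unrecoverable clusters emit nothing.
    """
    if cluster.status is None:
        raise ValueError("cluster has not been processed by repair_cluster")
    if cluster.status == "unrecoverable":
        return
    assert cluster.chosen is not None
    if keep_original and cluster.status in ("substituted", "repaired"):
        original = replace(cluster.centroid, tags=cluster.centroid.tags | {"original"})
        yield original
    yield cluster.chosen


def report_entry(cluster: Cluster) -> dict:
    """One repair-report JSON entry for a processed cluster."""
    if cluster.status is None:
        raise ValueError("cluster has not been processed by repair_cluster")
    return {
        "cluster_id": cluster.id,
        "original_centroid": cluster.centroid.bases,
        "chosen_sequence": cluster.chosen.bases if cluster.chosen else None,
        "edits": [e.to_dict() for e in cluster.edits],
        "n_changes": len(cluster.edits),
        "category": cluster.status,
    }
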
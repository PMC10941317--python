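"""Dereplication and greedy centroid clustering.

Sequencing a pool of oligos yields many reads per encoded sequence, most of
them exact duplicates.  Dereplication collapses identical strings into one
record carrying the total abundance; greedy clustering then merges near-
duplicates (erroneous descendants of one oligo) around high-priority
centroids, the same scheme used to build operational taxonomic units in
microbiome analysis.

The pool is ordered by abundance (or mean quality) and processed greedily:
pop the head as a new centroid, sweep every remaining sequence whose
similarity to it exceeds the threshold into the cluster, repeat.  Similarity
is ``1 - levenshtein(a, b) / max(len(a), len(b))`` — alignment-free and
monotone in edit distance, so a threshold of 0.97 on 100-nt reads admits
members within 3 edits of the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .io import SequenceRecord
from .repair import Cluster, edit_distance

DEFAULT_SIMILARITY_THRESHOLD = 0.97

ORDERS = ("abundance", "quality")


@dataclass
class ClusterParams:
    """Greedy-clustering knobs: similarity threshold (strict ``>``) and the
    pool ordering that decides which sequences become centroids."""

    threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    order: str = "abundance"

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}")


def dereplicate(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse identical base strings into single records.

    The representative's id and qualities come from the member with the
    highest mean quality (first seen wins ties; records without qualities
    rank lowest); its abundance is the sum over members, so total abundance
    is conserved.  Output preserves first-occurrence order.
    """
    groups: dict[str, SequenceRecord] = {}
    for rec in records:
        best = groups.get(rec.bases)
        if best is None:
            groups[rec.bases] = replace(rec, tags=set(rec.tags))
            continue
        best.abundance += rec.abundance
        if _mean_q_key(rec) > _mean_q_key(best):
            groups[rec.bases] = replace(
                rec, abundance=best.abundance, tags=best.tags | rec.tags
            )
    return list(groups.values())


def _mean_q_key(rec: SequenceRecord) -> float:
    q = rec.mean_quality()
    return -1.0 if q is None else q


def similarity(a: str, b: str) -> float:
    """``1 - edit_distance/max(len)``; two empty strings are identical (1.0)."""
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / longest


def _pool_key(rec: SequenceRecord, order: str):
    if order == "abundance":
        return (-rec.abundance, rec.id)
    return (-_mean_q_key(rec), rec.id)


def greedy_cluster(
    records: Iterable[SequenceRecord], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """Greedy similarity clustering of a dereplicated pool.

    Deterministic given the ordering keys; every input record lands in
    exactly one cluster, and every member's similarity to its centroid is
    strictly above the threshold.
    """
    pool = sorted(records, key=lambda r: _pool_key(r, params.order))
    clusters: list[Cluster] = []
    while pool:
        centroid = pool.pop(0)
        members = [centroid]
        remaining = []
        for rec in pool:
            if similarity(rec.bases, centroid.bases) > params.threshold:
                members.append(rec)
            else:
                remaining.append(rec)
        pool = remaining
        clusters.append(Cluster(centroid=centroid, members=members))
    return clusters


def membership_table(clusters: list[Cluster]) -> list[tuple[str, str, float]]:
    """(member id, centroid id, similarity) rows for a TSV membership dump."""
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append((m.id, cl.centroid.id, similarity(m.bases, cl.centroid.bases)))
    return rows
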
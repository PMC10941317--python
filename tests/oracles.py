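"""Independent brute-force oracles for cross-checking the library.

Everything here is deliberately naive (exhaustive scans, full DP tables,
complete edit-neighbourhood enumeration) and shares no code with the
implementation under test.
"""

from __future__ import annotations

from itertools import groupby
from typing import Iterator, Optional


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        row = [i]
        for j, cb in enumerate(b, 1):
            row.append(min(prev[j] + 1, row[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = row
    return prev[-1]


def naive_gc(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") / len(seq)


def naive_violations(seq, gc_min, gc_max, window, max_h, blacklist=(),
                     kmer_k=None, kmer_m=1, target_len=None):
    """Re-derive every violation by exhaustive scanning.

    Returns a set of (rule, start, end, magnitude) tuples with magnitudes
    rounded to 9 decimals for float-safe comparison.
    """
    out = set()
    n = len(seq)

    def gc_dev(frac):
        return round(gc_min - frac, 9) if frac < gc_min else (
            round(frac - gc_max, 9) if frac > gc_max else 0.0)

    if n:
        d = gc_dev(naive_gc(seq))
        if d:
            out.add(("gc_global", 0, n, d))
        for ws in range(0, n, window):
            we = min(ws + window, n)
            d = gc_dev(naive_gc(seq[ws:we]))
            if d:
                out.add(("gc_window", ws, we, d))
        # maximal runs via groupby
        pos = 0
        for base, grp in groupby(seq):
            r = len(list(grp))
            if r > max_h and base != "N":
                out.add(("homopolymer", pos, pos + r, float(r - max_h)))
            pos += r

    for motif in blacklist:
        for i in range(n - len(motif) + 1):
            if seq[i : i + len(motif)] == motif:
                out.add(("blacklist", i, i + len(motif), 1.0))

    if kmer_k is not None and n >= kmer_k:
        seen = set()
        for i in range(n - kmer_k + 1):
            kmer = seq[i : i + kmer_k]
            if kmer in seen:
                continue
            seen.add(kmer)
            hits = [j for j in range(n - kmer_k + 1) if seq[j : j + kmer_k] == kmer]
            if len(hits) > kmer_m:
                out.add(("kmer", hits[0], hits[-1] + kmer_k, float(len(hits) - kmer_m)))

    if target_len is not None and n != target_len:
        out.add(("length", 0, n, float(abs(n - target_len))))

    for i, c in enumerate(seq):
        if c == "N":
            out.add(("ambiguous", i, i + 1, 1.0))

    return out


def one_edit_variants(seq: str) -> Iterator[str]:
    """All sequences exactly one substitution/deletion/insertion away."""
    for i in range(len(seq)):
        for b in "ACGT":
            if b != seq[i]:
                yield seq[:i] + b + seq[i + 1 :]
        yield seq[:i] + seq[i + 1 :]
    for i in range(len(seq) + 1):
        for b in "ACGT":
            yield seq[:i] + b + seq[i:]


def valid_within_k_edits(seq: str, is_valid, k: int) -> Optional[str]:
    """Breadth-first search: any valid sequence within <= k edits, else None.

    ``is_valid`` is the validity predicate (constraint check) — shared with
    the implementation only through its public contract.
    """
    frontier = {seq}
    seen = {seq}
    for depth in range(k + 1):
        for s in frontier:
            if is_valid(s):
                return s
        if depth == k:
            break
        nxt = set()
        for s in frontier:
            for v in one_edit_variants(s):
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        frontier = nxt
    return None
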
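"""Constraint declaration, violation detection and the per-base error metric.

DNA-storage codes restrict their output codewords: bounded GC content
(globally and per window), bounded homopolymer runs, forbidden motifs,
limited k-mer repetition, and a fixed codeword length.  Because every
encoded oligo satisfies these rules, a violation observed in a sequencing
read is evidence of a synthesis/PCR/sequencing error — and *where* the
violation sits tells us which bases are suspect.

:func:`find_violations` reports every rule breach with an exact span;
:func:`error_profile` converts breaches into a per-base error score, the
quantity the maximum-likelihood repair loop greedily minimises.  Each rule's
contribution is designed so that editing a high-scoring base can actually
reduce the violation:

* homopolymer — every position of a violating run of length ``r`` scores
  ``(r - h) / r``;
* GC (window or global) — the deviation from the nearest bound, assigned
  only to bases whose identity aggravates it (G/C when too GC-rich, A/T
  when too GC-poor);
* blacklist — 1 for every position covered by a motif occurrence;
* k-mer — 1 for every position of an occurrence beyond the allowed count;
* length — drives ``length_delta`` only (repair fixes it with indels);
* N — always violates, scores 1.

Windows tile the sequence (offsets 0, w, 2w, ...); a trailing remainder
shorter than ``w`` is evaluated as its own window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

RULE_NAMES = (
    "gc_global",
    "gc_window",
    "homopolymer",
    "blacklist",
    "kmer",
    "length",
    "ambiguous",
)

_GC = frozenset("GC")
_AT = frozenset("AT")


@dataclass
class ConstraintSet:
    """The rule set an encoded oligo must satisfy.

    Defaults mirror the constraint values common in DNA-storage codes:
    GC in [0.40, 0.60] overall and per 15-base window, homopolymer runs of
    at most 3.  ``target_length`` may be an exact length or a
    ``(min, max)`` pair; ``None`` disables the length rule.  The k-mer rule
    ("no k-mer of length k may occur more than ``kmer_max_occurrences``
    times within one sequence") is off unless ``kmer_k`` is set.
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    window_size: int = 15
    gc_window_min: Optional[float] = None  # default: overall bounds
    gc_window_max: Optional[float] = None
    max_homopolymer: int = 3
    blacklist: list[str] = field(default_factory=list)
    kmer_k: Optional[int] = None
    kmer_max_occurrences: int = 1
    target_length: Optional[Union[int, tuple[int, int]]] = None
    rule_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if self.kmer_max_occurrences < 1:
            raise ValueError("kmer_max_occurrences must be >= 1")
        if self.gc_window_min is None:
            self.gc_window_min = self.gc_min
        if self.gc_window_max is None:
            self.gc_window_max = self.gc_max
        self.blacklist = [m.upper() for m in self.blacklist]
        for motif in self.blacklist:
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"blacklist motif {motif!r} must be nonempty over ACGT")
        for rule in self.rule_weights:
            if rule not in RULE_NAMES:
                raise ValueError(f"unknown rule {rule!r} in rule_weights")
            if self.rule_weights[rule] < 0:
                raise ValueError(f"weight for {rule!r} must be nonnegative")
        if isinstance(self.target_length, (list, tuple)):
            lo, hi = self.target_length
            if lo > hi:
                raise ValueError("target_length (min, max) must have min <= max")
            self.target_length = (int(lo), int(hi))

    def weight(self, rule: str) -> float:
        return self.rule_weights.get(rule, 1.0)

    def length_bounds(self) -> Optional[tuple[int, int]]:
        if self.target_length is None:
            return None
        if isinstance(self.target_length, tuple):
            return self.target_length
        return (self.target_length, self.target_length)

    def length_delta(self, n: int) -> int:
        """Signed distance of length ``n`` from the allowed range (0 inside)."""
        bounds = self.length_bounds()
        if bounds is None:
            return 0
        lo, hi = bounds
        if n < lo:
            return n - lo
        if n > hi:
            return n - hi
        return 0


@dataclass(frozen=True)
class Violation:
    """A located rule breach: 0-based half-open span and a severity."""

    rule: str
    start: int
    end: int
    magnitude: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ErrorProfile:
    """Per-base error scores plus the signed length mismatch."""

    scores: list[float]
    length_delta: int

    @property
    def total(self) -> float:
        return sum(self.scores)


def gc_fraction(bases: str, start: int = 0, end: Optional[int] = None) -> float:
    """(#G + #C) / span length over ``bases[start:end]``; N counts as neither."""
    if end is None:
        end = len(bases)
    if not (0 <= start < end <= len(bases)):
        raise ValueError(f"empty or out-of-range span [{start}, {end})")
    span = bases[start:end]
    return (span.count("G") + span.count("C")) / (end - start)


def _windows(n: int, w: int) -> list[tuple[int, int]]:
    """Tiling windows [0,w), [w,2w), ...; trailing remainder stands alone."""
    return [(s, min(s + w, n)) for s in range(0, n, w)]


def _runs(bases: str) -> list[tuple[int, int]]:
    """Maximal homopolymer runs as half-open spans."""
    runs = []
    start = 0
    for i in range(1, len(bases) + 1):
        if i == len(bases) or bases[i] != bases[start]:
            runs.append((start, i))
            start = i
    return runs


def _gc_deviation(frac: float, lo: float, hi: float) -> float:
    """Distance to the nearest bound; 0 inside [lo, hi]."""
    if frac < lo:
        return lo - frac
    if frac > hi:
        return frac - hi
    return 0.0


def _occurrences(bases: str, motif: str) -> list[int]:
    """All start positions of ``motif``, overlapping included."""
    out, start = [], 0
    while True:
        idx = bases.find(motif, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def find_violations(bases: str, cs: ConstraintSet) -> list[Violation]:
    """All rule breaches in ``bases``, each with an exact span.

    Severity (``magnitude``) is rule-specific: GC rules report the deviation
    from the nearest bound, homopolymer the excess run length ``r - h``,
    blacklist 1 per occurrence, k-mer the excess occurrence count, length
    ``|delta|``, and each N base 1.
    """
    n = len(bases)
    out: list[Violation] = []

    if n:
        dev = _gc_deviation(gc_fraction(bases), cs.gc_min, cs.gc_max)
        if dev > 0:
            out.append(Violation("gc_global", 0, n, dev))
        for ws, we in _windows(n, cs.window_size):
            dev = _gc_deviation(gc_fraction(bases, ws, we), cs.gc_window_min, cs.gc_window_max)
            if dev > 0:
                out.append(Violation("gc_window", ws, we, dev))
        for rs, re_ in _runs(bases):
            r = re_ - rs
            if r > cs.max_homopolymer and bases[rs] != "N":
                out.append(Violation("homopolymer", rs, re_, r - cs.max_homopolymer))

    for motif in cs.blacklist:
        for pos in _occurrences(bases, motif):
            out.append(Violation("blacklist", pos, pos + len(motif), 1.0))

    if cs.kmer_k is not None and n >= cs.kmer_k:
        k, m = cs.kmer_k, cs.kmer_max_occurrences
        counts: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            counts.setdefault(bases[i : i + k], []).append(i)
        for kmer in sorted(counts):
            positions = counts[kmer]
            if len(positions) > m:
                out.append(
                    Violation("kmer", positions[0], positions[-1] + k, len(positions) - m)
                )

    delta = cs.length_delta(n)
    if delta != 0:
        out.append(Violation("length", 0, n, abs(delta)))

    for i, b in enumerate(bases):
        if b == "N":
            out.append(Violation("ambiguous", i, i + 1, 1.0))

    return out


def error_profile(bases: str, cs: ConstraintSet) -> ErrorProfile:
    """Per-base error scores: weighted sum of each rule's contribution.

    A sequence with no violations scores all-zero with ``length_delta`` 0;
    conversely any non-length violation puts positive mass on at least one
    base, so the greedy repair always has a target.
    """
    n = len(bases)
    scores = [0.0] * n

    for v in find_violations(bases, cs):
        w = cs.weight(v.rule)
        if w == 0:
            continue
        if v.rule == "homopolymer":
            r = v.end - v.start
            contribution = (r - cs.max_homopolymer) / r
            for i in range(v.start, v.end):
                scores[i] += w * contribution
        elif v.rule in ("gc_global", "gc_window"):
            lo = cs.gc_min if v.rule == "gc_global" else cs.gc_window_min
            frac = gc_fraction(bases, v.start, v.end)
            aggravating = _GC if frac > lo else _AT  # too rich vs too poor
            for i in range(v.start, v.end):
                if bases[i] in aggravating:
                    scores[i] += w * v.magnitude
        elif v.rule == "blacklist":
            for i in range(v.start, v.end):
                scores[i] += w
        elif v.rule == "kmer":
            # only occurrences beyond the allowed count carry error mass;
            # the first m occurrences are treated as legitimate
            k = cs.kmer_k
            assert k is not None
            kmer = bases[v.start : v.start + k]
            for pos in _occurrences(bases, kmer)[cs.kmer_max_occurrences :]:
                for i in range(pos, pos + k):
                    scores[i] += w
        elif v.rule == "ambiguous":
            scores[v.start] += w
        # length contributes to length_delta only

    return ErrorProfile(scores=scores, length_delta=cs.length_delta(n))


def violation_penalty(bases: str, cs: ConstraintSet) -> float:
    """Weighted violation count, the sort-mode penalty: sum of w_rule per breach."""
    return sum(cs.weight(v.rule) for v in find_violations(bases, cs))


def max_homopolymer_run(bases: str) -> int:
    """Length of the longest run of identical bases (0 for empty input)."""
    if not bases:
        return 0
    return max(e - s for s, e in _runs(bases))
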
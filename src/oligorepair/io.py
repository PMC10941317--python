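"""File formats and core record types.

Reads arrive as FASTQ (Sanger/+33 PHRED) or FASTA; dereplicated pools are
written as FASTA with the USEARCH ``;size=N`` abundance annotation; sample
metadata comes from a delimited primer table; repair outcomes are written as
a JSON report validating against the schema shipped with the package
(``report_schema.json``).

Only the bases A, C, G, T and N are accepted on input: the constraint
arithmetic downstream is defined over {A,C,G,T}, with N treated as an
always-violating placeholder.  Other IUPAC ambiguity codes are rejected.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33  # Sanger encoding, universal for modern Illumina/Nanopore FASTQ
PHRED_MAX = 93  # highest score representable in printable ASCII at +33

_VALID_BASES = frozenset("ACGTN")
_SIZE_RE = re.compile(r";size=(\d+)$")


class FormatError(ValueError):
    """Raised for malformed input files (bad FASTQ records, primer tables...)."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """One read (or dereplicated read group) moving through the pipeline.

    Parameters
    ----------
    id:
        Read label, taken from the FASTQ/FASTA header up to the first
        whitespace.
    bases:
        Upper-case sequence over ``{A, C, G, T, N}``.
    quals:
        Per-base integer PHRED scores (``Q = -10 log10 Pe``), one per base;
        ``None`` for FASTA input.
    abundance:
        Number of identical reads this record represents (``>= 1``).
    tags:
        Processing flags such as ``"correct"``, ``"substituted"``,
        ``"repaired:2"`` or ``"original"``.
    """

    id: str
    bases: str
    quals: Optional[list[int]] = None
    abundance: int = 1
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid bases {sorted(bad)}; "
                "only A,C,G,T,N are supported"
            )
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise FormatError(
                    f"record {self.id!r}: {len(self.quals)} quality scores "
                    f"for {len(self.bases)} bases"
                )
            if any(q < 0 or q > PHRED_MAX for q in self.quals):
                raise FormatError(f"record {self.id!r}: PHRED score outside [0, {PHRED_MAX}]")
        if self.abundance < 1:
            raise FormatError(f"record {self.id!r}: abundance must be >= 1")

    def __len__(self) -> int:
        return len(self.bases)

    def mean_quality(self) -> Optional[float]:
        """Arithmetic mean of the PHRED scores, or ``None`` without qualities."""
        if not self.quals:
            return None
        return sum(self.quals) / len(self.quals)


@dataclass
class PrimerRow:
    """Per-sample demultiplexing/trimming instructions.

    Each side (forward / reverse) carries either a primer *sequence* to match
    and strip, or a fixed trim *length* — never both.
    """

    sample: str
    barcode: Optional[str] = None
    fprimer: Optional[str] = None
    fprimer_len: Optional[int] = None
    rprimer: Optional[str] = None
    rprimer_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fprimer is not None and self.fprimer_len is not None:
            raise FormatError(
                f"sample {self.sample!r}: forward primer given both as sequence and length"
            )
        if self.rprimer is not None and self.rprimer_len is not None:
            raise FormatError(
                f"sample {self.sample!r}: reverse primer given both as sequence and length"
            )


@dataclass
class PrimerTable:
    rows: dict[str, PrimerRow]

    def __getitem__(self, sample: str) -> PrimerRow:
        return self.rows[sample]

    def __iter__(self) -> Iterator[PrimerRow]:
        return iter(self.rows.values())

    def barcodes(self) -> dict[str, str]:
        """Map barcode sequence -> sample name (error on duplicates)."""
        out: dict[str, str] = {}
        for row in self:
            if row.barcode:
                if row.barcode in out:
                    raise FormatError(
                        f"barcode {row.barcode!r} shared by samples "
                        f"{out[row.barcode]!r} and {row.sample!r}"
                    )
                out[row.barcode] = row.sample
        return out


# ---------------------------------------------------------------------------
# PHRED arithmetic
# ---------------------------------------------------------------------------


def phred_from_prob(pe: float) -> float:
    """Quality score for an error probability: ``Q = -10 * log10(Pe)``."""
    if pe <= 0:
        raise ValueError(f"error probability must be > 0, got {pe}")
    if pe > 1:
        raise ValueError(f"error probability must be <= 1, got {pe}")
    return -10.0 * math.log10(pe)


def prob_from_phred(q: float) -> float:
    """Inverse of :func:`phred_from_prob`: ``Pe = 10**(-Q/10)``."""
    return 10.0 ** (-q / 10.0)


def encode_quals(quals: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def decode_quals(qual_string: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual_string]


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: Union[str, Path]) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line FASTQ file (Sanger +33 qualities).

    Malformed records (missing ``+`` separator, quality/sequence length
    mismatch) raise :class:`FormatError` naming the record index.
    """
    path = Path(path)
    with path.open() as handle:
        yield from _parse_fastq(handle, str(path))


def _parse_fastq(handle: TextIO, source: str) -> Iterator[SequenceRecord]:
    index = 0
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.strip():
            continue
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not header.startswith("@"):
            raise FormatError(f"{source}: record {index}: header does not start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{source}: record {index}: missing '+' separator line")
        if len(qual) != len(seq):
            raise FormatError(
                f"{source}: record {index}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        rec_id = header[1:].split()[0] if header[1:].split() else header[1:]
        yield SequenceRecord(id=rec_id, bases=seq, quals=decode_quals(qual))
        index += 1


def write_fastq(records: Iterable[SequenceRecord], path: Union[str, Path]) -> int:
    """Write records as 4-line FASTQ; records must carry qualities."""
    n = 0
    with Path(path).open("w") as out:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            out.write(f"@{_format_header(rec)}\n{rec.bases}\n+\n{encode_quals(rec.quals)}\n")
            n += 1
    return n


def read_fasta(path: Union[str, Path]) -> Iterator[SequenceRecord]:
    """Stream records from FASTA; ``;size=N`` header suffixes restore abundance."""
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, abundance = _parse_size(rec.id)
        yield SequenceRecord(id=rec_id, bases=str(rec.seq), abundance=abundance)


def _parse_size(header_id: str) -> tuple[str, int]:
    m = _SIZE_RE.search(header_id)
    if m:
        return header_id[: m.start()], int(m.group(1))
    return header_id, 1


def _format_header(rec: SequenceRecord) -> str:
    head = rec.id
    if rec.tags:
        head += " " + ";".join(sorted(rec.tags))
    return head


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> int:
    """Plain FASTA output (no abundance annotation)."""
    recs = (SeqRecord(Seq(r.bases), id=_format_header(r), description="") for r in records)
    return SeqIO.write(recs, str(path), "fasta-2line")


def write_fasta_derep(records: Iterable[SequenceRecord], path: Union[str, Path]) -> int:
    """FASTA with the dereplication dialect: headers carry ``;size=N``."""
    recs = []
    for r in records:
        head = f"{r.id};size={r.abundance}"
        if r.tags:
            head = f"{r.id};size={r.abundance} " + ";".join(sorted(r.tags))
        recs.append(SeqRecord(Seq(r.bases), id=head.split(" ")[0],
                              description=" ".join(head.split(" ")[1:])))
    return SeqIO.write(recs, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Primer table
# ---------------------------------------------------------------------------

_PRIMER_COLUMNS = {"sample", "barcode", "fprimer", "rprimer"}


def read_primer_table(path: Union[str, Path]) -> PrimerTable:
    """Parse a delimited primer table (comma or tab auto-detected).

    Expected header: ``sample,barcode,fprimer,rprimer``.  A primer field is
    either a base sequence or an integer trim length; empty fields mean
    "absent".  Duplicate sample names are an error.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows: dict[str, PrimerRow] = {}
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    if reader.fieldnames is None or "sample" not in reader.fieldnames:
        raise FormatError(f"{path}: primer table needs a header with a 'sample' column")
    unknown = set(reader.fieldnames) - _PRIMER_COLUMNS
    if unknown:
        raise FormatError(f"{path}: unknown primer-table columns {sorted(unknown)}")
    for raw in reader:
        sample = (raw.get("sample") or "").strip()
        if not sample:
            raise FormatError(f"{path}: row with empty sample name")
        if sample in rows:
            raise FormatError(f"{path}: duplicate sample name {sample!r}")
        fseq, flen = _parse_primer_field(raw.get("fprimer"), path, sample, "fprimer")
        rseq, rlen = _parse_primer_field(raw.get("rprimer"), path, sample, "rprimer")
        barcode = (raw.get("barcode") or "").strip().upper() or None
        rows[sample] = PrimerRow(
            sample=sample, barcode=barcode,
            fprimer=fseq, fprimer_len=flen, rprimer=rseq, rprimer_len=rlen,
        )
    table = PrimerTable(rows)
    table.barcodes()  # fail fast on shared barcodes
    return table


def _parse_primer_field(
    value: Optional[str], path: Path, sample: str, side: str
) -> tuple[Optional[str], Optional[int]]:
    value = (value or "").strip()
    if not value:
        return None, None
    if value.isdigit():
        return None, int(value)
    seq = value.upper()
    if set(seq) - set("ACGTN"):
        raise FormatError(f"{path}: sample {sample!r}: {side} {value!r} is neither "
                          "a base sequence nor a trim length")
    return seq, None


# ---------------------------------------------------------------------------
# Repair report
# ---------------------------------------------------------------------------

REPORT_CATEGORIES = ("correct", "substituted", "repaired", "unrecoverable")


def report_schema() -> dict:
    """The JSON schema (draft-07) the repair report validates against."""
    schema_path = Path(__file__).parent / "report_schema.json"
    return json.loads(schema_path.read_text())


def validate_report(report: dict) -> None:
    """Structural validation of a repair report against the shipped schema.

    Raises ``ValueError`` on the first breach (wrong types, unknown category,
    change count not matching the edit list, non-empty edits on a "correct"
    entry).
    """
    if not isinstance(report, dict):
        raise ValueError("report must be an object mapping file name -> entries")
    for fname, entries in report.items():
        if not isinstance(entries, list):
            raise ValueError(f"report[{fname!r}] must be a list of cluster entries")
        for i, e in enumerate(entries):
            where = f"report[{fname!r}][{i}]"
            for key in ("cluster_id", "original_centroid", "chosen_sequence",
                        "edits", "n_changes", "category"):
                if key not in e:
                    raise ValueError(f"{where}: missing field {key!r}")
            if e["category"] not in REPORT_CATEGORIES:
                raise ValueError(f"{where}: unknown category {e['category']!r}")
            if not isinstance(e["edits"], list):
                raise ValueError(f"{where}: edits must be a list")
            if e["n_changes"] != len(e["edits"]):
                raise ValueError(
                    f"{where}: n_changes {e['n_changes']} != {len(e['edits'])} edits"
                )
            if e["category"] == "correct" and e["edits"]:
                raise ValueError(f"{where}: 'correct' entry must have an empty edit list")
            for j, edit in enumerate(e["edits"]):
                if not isinstance(edit, dict) or "op" not in edit or "position" not in edit:
                    raise ValueError(f"{where}: edit {j} must carry 'op' and 'position'")
                if edit["op"] not in ("substitution", "deletion", "insertion"):
                    raise ValueError(f"{where}: edit {j}: unknown op {edit['op']!r}")


def write_report(report: dict, path: Union[str, Path]) -> None:
    """Validate and write a repair report as pretty-printed JSON."""
    validate_report(report)
    with Path(path).open("w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
        out.write("\n")


def read_report(path: Union[str, Path]) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report
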
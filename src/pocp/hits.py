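"""The AlignmentHit record and BLAST/DIAMOND tabular (outfmt 6) parsing.

AlignmentHit is the common currency between the built-in aligner and
externally produced hit tables: it carries exactly the quantities the
conservation filters read (e-value, percent identity, and the query span
from which coverage is derived).

Conventions follow the outfmt-6 standard: qstart/qend are 1-based
inclusive; percent identity uses the BLAST "pident" denominator (all
alignment columns, including gap columns); query coverage is the
qstart..qend span over the query length, so gaps in the query do not
inflate coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

from .errors import InputError, ParseError
from .fasta_io import Proteome

if TYPE_CHECKING:  # pragma: no cover
    from .aligner import LocalAlignment

#: Standard 12-column outfmt-6 field order.
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-subject local alignment record."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_columns: int
    query_start: int
    query_end: int
    evalue: float
    score: float  # bitscore (external tables) or raw score (internal aligner)
    query_len: int

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise InputError(
                f"hit {self.query_id} vs {self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.align_columns < 1:
            raise InputError(
                f"hit {self.query_id} vs {self.subject_id}: alignment length must be >= 1"
            )
        if not (1 <= self.query_start <= self.query_end <= self.query_len):
            raise InputError(
                f"hit {self.query_id} vs {self.subject_id}: query span "
                f"{self.query_start}..{self.query_end} invalid for length {self.query_len}"
            )
        if self.evalue < 0:
            raise InputError(
                f"hit {self.query_id} vs {self.subject_id}: negative e-value"
            )

    @property
    def query_coverage(self) -> float:
        """Aligned query span as a percentage of query length, in (0, 100]."""
        return 100.0 * (self.query_end - self.query_start + 1) / self.query_len


def from_local_alignment(aln: "LocalAlignment", query_len: int) -> AlignmentHit:
    """Convert an internal alignment to a hit; pident counts gap columns."""
    return AlignmentHit(
        query_id=aln.query_id,
        subject_id=aln.subject_id,
        percent_identity=100.0 * aln.n_identical / aln.n_columns,
        align_columns=aln.n_columns,
        query_start=aln.query_start,
        query_end=aln.query_end,
        evalue=aln.evalue,
        score=float(aln.score),
        query_len=query_len,
    )


def _num(value: str, line_no: int, column: str, kind=float):
    try:
        return kind(value)
    except ValueError:
        raise ParseError(
            f"column '{column}': cannot parse '{value}' as a number", line=line_no
        ) from None


def parse_tabular_hits(path: str | Path, query_proteome: Proteome | None = None) -> list[AlignmentHit]:
    """Parse 12- or 13-column BLAST/DIAMOND tabular output.

    The 13th column, when present, is qlen; otherwise query lengths are
    looked up by qseqid in *query_proteome*. Rows keep file order;
    '#'-prefixed comment lines and blank lines are skipped. An empty file is
    a valid "no hits" outcome and yields an empty list.
    """
    path = Path(path)
    lengths = query_proteome.lengths_by_id() if query_proteome is not None else {}
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ParseError(
                    f"expected 12 or 13 tab-separated columns, found {len(fields)}",
                    line=line_no,
                )
            qseqid, sseqid = fields[0], fields[1]
            if len(fields) == 13:
                qlen = _num(fields[12], line_no, "qlen", int)
            else:
                if query_proteome is None:
                    raise InputError(
                        f"{path}: 12-column table requires a query proteome for qlen lookup"
                    )
                if qseqid not in lengths:
                    raise InputError(
                        f"{path}: query id '{qseqid}' (line {line_no}) not found in "
                        f"proteome '{query_proteome.label}'"
                    )
                qlen = lengths[qseqid]
            hits.append(
                AlignmentHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    percent_identity=_num(fields[2], line_no, "pident"),
                    align_columns=_num(fields[3], line_no, "length", int),
                    query_start=_num(fields[6], line_no, "qstart", int),
                    query_end=_num(fields[7], line_no, "qend", int),
                    evalue=_num(fields[10], line_no, "evalue"),
                    score=_num(fields[11], line_no, "bitscore"),
                    query_len=qlen,
                )
            )
    return hits


def write_tabular_hits(
    hits: list[AlignmentHit], path: str | Path, include_qlen: bool = True
) -> None:
    """Serialize hits as outfmt-6 rows (mismatch/gapopen/sstart/send are not
    tracked by this package and are written as 0)."""
    with open(path, "w") as handle:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:g}",
                str(h.align_columns),
                "0",
                "0",
                str(h.query_start),
                str(h.query_end),
                "0",
                "0",
                f"{h.evalue:g}",
                f"{h.score:g}",
            ]
            if include_qlen:
                fields.append(str(h.query_len))
            handle.write("\t".join(fields) + "\n")
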
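"""Protein multi-FASTA input, validation, and proteome labelling.

One FASTA file per genome/strain. Record ids are the first
whitespace-delimited header token — the same token BLAST/DIAMOND report in
tabular output, so ids join cleanly against external hit tables. Trailing
stop codons (``*``) are stripped; internal stops are rejected because they
indicate a frame problem upstream of this tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import InputError

#: The 20 canonical amino acids.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted after sanitization (canonical + ambiguity codes B, Z, X).
ACCEPTED_ALPHABET = frozenset(CANONICAL_RESIDUES) | frozenset("XBZ")

#: Nonstandard residues mapped to X: selenocysteine (U), pyrrolysine (O),
#: and the I/L ambiguity code (J).
RESIDUE_SUBSTITUTIONS = {"U": "X", "O": "X", "J": "X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its FASTA id."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A labelled, ordered set of protein records for one genome/strain."""

    label: str
    records: list[ProteinRecord] = field(default_factory=list)

    @property
    def total_proteins(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def lengths_by_id(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}

    def relabelled(self, label: str) -> "Proteome":
        """Same records under a new label (useful for self-comparison checks)."""
        return Proteome(label=label, records=list(self.records))


def sanitize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, strip trailing stops, map U/O/J to X; reject anything else.

    Raises :class:`InputError` naming the record and 1-based residue position
    for characters that cannot be mapped into the accepted alphabet, and for
    internal stop codons.
    """
    seq = raw.upper().replace(" ", "")
    stripped = seq.rstrip("*")
    n_trailing_stops = len(seq) - len(stripped)
    out = []
    for pos, ch in enumerate(stripped, start=1):
        if ch in ACCEPTED_ALPHABET:
            out.append(ch)
        elif ch in RESIDUE_SUBSTITUTIONS:
            out.append(RESIDUE_SUBSTITUTIONS[ch])
        elif ch == "*":
            raise InputError(
                f"record '{record_id}': internal stop codon '*' at position {pos}; "
                "internal stops usually indicate a frame problem in the annotation"
            )
        else:
            raise InputError(
                f"record '{record_id}': character '{ch}' at position {pos} is not "
                "a recognized amino-acid code"
            )
    result = "".join(out)
    if not result:
        detail = "only stop codons" if n_trailing_stops else "no residues"
        raise InputError(f"record '{record_id}': empty sequence ({detail})")
    return result


def label_from_path(path: str | Path) -> str:
    """Basename with the last extension stripped ('ecoli_k12.faa' -> 'ecoli_k12')."""
    return Path(path).stem


def read_protein_fasta(path: str | Path, label: str | None = None) -> Proteome:
    """Read a protein multi-FASTA file into a :class:`Proteome`.

    Records preserve file order. The record id is the first
    whitespace-delimited header token. If *label* is omitted it is derived
    from the file name via :func:`label_from_path`.

    Raises
    ------
    InputError
        For an empty file, duplicate record ids, or unmappable residues.
    """
    path = Path(path)
    if label is None:
        label = label_from_path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise InputError(f"{path}: record with empty header")
            if rec_id in seen:
                raise InputError(f"{path}: duplicate record id '{rec_id}'")
            seen.add(rec_id)
            records.append(ProteinRecord(id=rec_id, sequence=sanitize_sequence(seq, rec_id)))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return Proteome(label=label, records=records)


def write_protein_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as standard wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in proteome.records:
            handle.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.sequence[i : i + width] + "\n")


def validate_run_inputs(proteomes: list[Proteome], minimum: int = 2) -> list[Proteome]:
    """Single entry gate before comparison: unique labels, enough proteomes.

    Returns the list unchanged on success.
    """
    if not proteomes:
        raise InputError("no input proteomes")
    if len(proteomes) < minimum:
        raise InputError(
            f"need at least {minimum} proteomes for pairwise comparison, got {len(proteomes)}"
        )
    seen: dict[str, int] = {}
    collisions = []
    for p in proteomes:
        seen[p.label] = seen.get(p.label, 0) + 1
    collisions = sorted(lbl for lbl, n in seen.items() if n > 1)
    if collisions:
        raise InputError(f"duplicate proteome labels: {', '.join(collisions)}")
    for p in proteomes:
        if p.total_proteins < 1:
            raise InputError(f"proteome '{p.label}' has no records")
    return proteomes
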
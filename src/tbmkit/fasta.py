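"""FASTA input/output with native protein residue numbering.

Peptide fragments (e.g. a C-terminal peptide spanning residues 391-403 of a
full-length protein) keep their native numbering through a ``start_residue``
offset, declared in the FASTA header as a ``start=<n>`` token.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Scannable alphabet: the 20 standard residues plus 'X' for unknown.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP_CHARS = frozenset("-.")

_START_TOKEN = re.compile(r"\s*\bstart=(\d+)\b")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad residues, duplicate ids)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a 1-based start-residue offset.

    ``start_residue`` is the residue number of the first sequence character,
    so ``record.residue(n)`` returns the amino acid at protein position ``n``.
    """

    id: str
    sequence: str
    description: str = ""
    start_residue: int = 1

    def __post_init__(self) -> None:
        if self.start_residue < 1:
            raise ValueError(
                f"start_residue must be >= 1, got {self.start_residue}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_residue(self) -> int:
        """Residue number of the last sequence character (inclusive)."""
        return self.start_residue + len(self.sequence) - 1

    def residue(self, number: int) -> str:
        """Amino acid at protein residue ``number`` (1-based, native)."""
        idx = number - self.start_residue
        if not 0 <= idx < len(self.sequence):
            raise IndexError(
                f"residue {number} outside {self.id} "
                f"[{self.start_residue}, {self.end_residue}]"
            )
        return self.sequence[idx]

    def with_start(self, start_residue: int) -> "ProteinRecord":
        return replace(self, start_residue=start_residue)


Source = Union[str, Path, IO[str]]


def _as_handle(source: Source) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text_or_path = str(source)
    if "\n" in text_or_path or text_or_path.startswith(">"):
        return io.StringIO(text_or_path)
    return open(text_or_path)


def _validate(seq: str, rec_id: str, allow_gaps: bool) -> None:
    allowed = VALID_RESIDUES | GAP_CHARS if allow_gaps else VALID_RESIDUES
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise FastaFormatError(
                f"record '{rec_id}': invalid character {ch!r} at position {pos}"
            )


def _parse(source: Source, allow_gaps: bool) -> list[ProteinRecord]:
    handle = _as_handle(source)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"duplicate record id '{rec.id}'")
            seen.add(rec.id)
            seq = str(rec.seq).upper().replace(" ", "")
            _validate(seq, rec.id, allow_gaps)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):]
            start = 1
            m = _START_TOKEN.search(desc)
            if m:
                start = int(m.group(1))
                desc = _START_TOKEN.sub("", desc, count=1)
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=seq,
                    description=desc.strip(),
                    start_residue=start,
                )
            )
    finally:
        if handle is not source:
            handle.close()
    return records


def read_fasta(source: Source) -> list[ProteinRecord]:
    """Read protein records from FASTA text, a path, or a file handle.

    A header token ``start=<n>`` sets the record's ``start_residue``.
    Sequences are uppercased; whitespace is stripped; input order preserved.

    Raises
    ------
    FastaFormatError
        On non-amino-acid characters (naming record and position) or
        duplicate record ids.
    """
    return _parse(source, allow_gaps=False)


def read_alignment(source: Source) -> list[ProteinRecord]:
    """Read an aligned FASTA (gaps ``-``/``.`` permitted, kept as ``-``)."""
    records = _parse(source, allow_gaps=True)
    return [replace(r, sequence=r.sequence.replace(".", "-")) for r in records]


def format_fasta(records: Iterable[ProteinRecord], width: int = 60) -> str:
    """Render records as FASTA text (inverse of :func:`read_fasta`)."""
    chunks: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.start_residue != 1:
            header += f" start={rec.start_residue}"
        if rec.description:
            header += f" {rec.description}"
        chunks.append(header)
        for i in range(0, len(rec.sequence), width):
            chunks.append(rec.sequence[i : i + width])
    return "\n".join(chunks) + "\n"


def write_fasta(
    records: Iterable[ProteinRecord], target: Union[str, Path, IO[str]],
    width: int = 60,
) -> None:
    text = format_fasta(records, width=width)
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        Path(target).write_text(text)
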
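"""Consensus scanning for the TMEM55B-binding motif (TBM).

The TBM is a short linear motif, E-x-(G/A)-x-E-A, anchored by glutamates at
motif positions 1 and 5 ('x' is any residue).  The strict pattern carries the
position-6 alanine; the relaxed pattern admits glutamine as the first anchor
and drops position 6, accommodating the OCRL-type variant (Q at position 1,
T at position 6).

Coordinates throughout are 1-based, inclusive, in native protein numbering,
so hits line up with mutagenesis labels such as E398 of RILPL1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fasta import AMINO_ACIDS, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of allowed-residue sets; ``None`` marks a wildcard.

    ``anchor_positions`` are 1-based indices within the motif marking the two
    glutamate anchors (positions 1 and 5 for the shipped TBM patterns).
    """

    name: str
    positions: tuple[Optional[frozenset[str]], ...]
    anchor_positions: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("pattern must have length >= 2")
        for a in self.anchor_positions:
            if not 1 <= a <= len(self.positions):
                raise ValueError(
                    f"anchor position {a} outside pattern of length "
                    f"{len(self.positions)}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, offset: int) -> bool:
        """True if the pattern matches ``sequence`` at 0-based ``offset``.

        'X' never satisfies a constrained position and always satisfies a
        wildcard.
        """
        if offset < 0 or offset + len(self.positions) > len(sequence):
            return False
        for allowed, ch in zip(self.positions, sequence[offset:]):
            if allowed is not None and ch not in allowed:
                return False
        return True


def _sets(*specs: Optional[str]) -> tuple[Optional[frozenset[str]], ...]:
    return tuple(None if s is None else frozenset(s) for s in specs)


#: Strict consensus E-x-(G/A)-x-E-A.
STRICT_TBM = MotifPattern(
    "strict", _sets("E", None, "GA", None, "E", "A"), (1, 5)
)
#: Relaxed consensus (E/Q)-x-(G/A)-x-E; position 6 unconstrained.
RELAXED_TBM = MotifPattern(
    "relaxed", _sets("EQ", None, "GA", None, "E"), (1, 5)
)

PATTERNS = {"strict": STRICT_TBM, "relaxed": RELAXED_TBM}


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in native protein coordinates (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    matched_sequence: str
    anchor1_residue: int
    anchor2_residue: int
    pattern_name: str
    score: Optional[float] = None


def scan_motif(record: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """Report every match of ``pattern`` in ``record``, left to right.

    Overlapping hits are all reported; a sequence shorter than the pattern
    yields an empty list.  Coordinates are converted through the record's
    ``start_residue``.
    """
    if not record.sequence:
        raise ValueError(f"record '{record.id}' has an empty sequence")
    a1, a2 = pattern.anchor_positions
    hits: list[MotifHit] = []
    length = len(pattern)
    for offset in range(len(record.sequence) - length + 1):
        if pattern.matches_at(record.sequence, offset):
            start = record.start_residue + offset
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    start=start,
                    end=start + length - 1,
                    matched_sequence=record.sequence[offset : offset + length],
                    anchor1_residue=start + a1 - 1,
                    anchor2_residue=start + a2 - 1,
                    pattern_name=pattern.name,
                )
            )
    return hits


def scan_records(
    records: Iterable[ProteinRecord],
    patterns: Sequence[MotifPattern] = (STRICT_TBM, RELAXED_TBM),
) -> list[MotifHit]:
    """Scan every record with every pattern (convenience wrapper)."""
    hits: list[MotifHit] = []
    for rec in records:
        for pat in patterns:
            hits.extend(scan_motif(rec, pat))
    return hits


# ---------------------------------------------------------------------------
# Position-specific scoring
# ---------------------------------------------------------------------------

def build_pssm(
    aligned_motifs: Sequence[str], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Log-odds position score matrix from equal-length aligned motif strings.

    Scores are natural-log odds against a uniform 1/20 background, so for
    each column ``sum_a (1/20) * exp(score_a) == 1`` exactly.

    Parameters
    ----------
    aligned_motifs : equal-length uppercase amino-acid strings
    pseudocount : added to every residue count per column; must be > 0

    Returns
    -------
    DataFrame of shape (motif length, 20), index = motif position (1-based),
    columns = amino acids.
    """
    if not aligned_motifs:
        raise ValueError("no motifs supplied")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    length = len(aligned_motifs[0])
    counts = np.zeros((length, 20))
    for seq in aligned_motifs:
        if len(seq) != length:
            raise ValueError(
                f"ragged input: expected length {length}, got {len(seq)} "
                f"in {seq!r}"
            )
        for j, ch in enumerate(seq.upper()):
            if ch not in _AA_INDEX:
                raise ValueError(f"invalid residue {ch!r} in {seq!r}")
            counts[j, _AA_INDEX[ch]] += 1
    probs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )
    scores = np.log(probs * 20.0)
    return pd.DataFrame(
        scores, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )


def column_information(pssm_or_motifs, pseudocount: float = 1e-9) -> np.ndarray:
    """Per-column information content (bits) of aligned motif strings."""
    if isinstance(pssm_or_motifs, pd.DataFrame):
        probs = np.exp(pssm_or_motifs.to_numpy()) / 20.0
    else:
        probs = np.exp(
            build_pssm(pssm_or_motifs, pseudocount=pseudocount).to_numpy()
        ) / 20.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    return np.log2(20.0) + plogp.sum(axis=1)


def score_hit(hit: MotifHit, pssm: pd.DataFrame) -> float:
    """Sum of per-position log-odds for a hit; residue 'X' scores 0."""
    if len(hit.matched_sequence) != len(pssm):
        raise ValueError(
            f"hit length {len(hit.matched_sequence)} != PSSM length {len(pssm)}"
        )
    total = 0.0
    matrix = pssm.to_numpy()
    for j, ch in enumerate(hit.matched_sequence):
        if ch == "X":
            continue
        total += matrix[j, _AA_INDEX[ch]]
    return float(total)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "protein_id", "start", "end", "pattern",
    "matched_sequence", "anchor1", "anchor2", "score",
]


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": h.protein_id,
            "start": h.start,
            "end": h.end,
            "pattern": h.pattern_name,
            "matched_sequence": h.matched_sequence,
            "anchor1": h.anchor1_residue,
            "anchor2": h.anchor2_residue,
            "score": h.score,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[MotifHit]:
    hits = []
    for row in frame.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and pd.isna(score):
            score = None
        hits.append(
            MotifHit(
                protein_id=row.protein_id,
                start=int(row.start),
                end=int(row.end),
                matched_sequence=row.matched_sequence,
                anchor1_residue=int(row.anchor1),
                anchor2_residue=int(row.anchor2),
                pattern_name=row.pattern,
                score=score,
            )
        )
    return hits


def write_hits_tsv(
    hits: Iterable[MotifHit], target: Union[str, Path, IO[str]]
) -> None:
    hits_to_frame(hits).to_csv(target, sep="\t", index=False)


def read_hits_tsv(source: Union[str, Path, IO[str]]) -> list[MotifHit]:
    return frame_to_hits(pd.read_csv(source, sep="\t", comment="#"))
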
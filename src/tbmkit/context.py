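"""Candidate filtering for motif hits: conservation, flexibility, exposure.

A genuine TBM must sit in a flexible, surface-exposed stretch of polypeptide
(free to make backbone hydrogen bonds with the receptor) and show some
evolutionary conservation at its glutamate anchors.  Motif matches predicted
to form inaccessible parts of alpha-helices or beta-strands are excluded.

Three per-residue evidence tracks feed the verdict:

* secondary structure (3-state H/E/C, 'U' for unknown) together with pLDDT
  confidence (predicted-model B-factor convention; values below ~70 proxy
  flexibility),
* relative solvent accessibility (rSASA in [0, 1]),
* a column-conservation profile computed from a multiple sequence alignment.

Missing tracks are recorded as ``no_data`` notes, never as failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fasta import ProteinRecord
from .motif import MotifHit

# Kyte-Doolittle hydropathy, used rescaled to [0, 1] by (h + 4.5) / 9.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def disorder_profile(sequence: str, window: int = 21) -> np.ndarray:
    """Windowed foldability index; negative values flag disorder-prone residues.

    Per window the score is ``I = 2.785 * <H> - |<q>| - 1.151`` where ``<H>``
    is mean Kyte-Doolittle hydropathy rescaled to [0, 1] and ``<q>`` the mean
    net charge (D/E = -1, K/R = +1).  Windows are truncated at the termini so
    the output has one value per residue.
    """
    n = len(sequence)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > n:
        raise ValueError(f"window {window} larger than sequence length {n}")
    hydro = np.array([(KYTE_DOOLITTLE[ch] + 4.5) / 9.0 for ch in sequence])
    charge = np.array([_CHARGE.get(ch, 0.0) for ch in sequence])
    half = window // 2
    mean_h = (
        pd.Series(hydro).rolling(window, center=True, min_periods=1).mean()
    )
    mean_q = (
        pd.Series(charge).rolling(window, center=True, min_periods=1).mean()
    )
    return (2.785 * mean_h - mean_q.abs() - 1.151).to_numpy()


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per-reference-residue conservation scores in [0, 1].

    ``no_data`` flags columns where no non-reference row carries a residue.
    """

    reference_id: str
    residue_numbers: np.ndarray
    scores: np.ndarray
    no_data: np.ndarray

    def score_at(self, residue_number: int) -> Optional[float]:
        """Score at a native residue number, or None if absent / no data."""
        idx = np.nonzero(self.residue_numbers == residue_number)[0]
        if idx.size == 0 or self.no_data[idx[0]]:
            return None
        return float(self.scores[idx[0]])


def conservation_scores(
    msa: Sequence[ProteinRecord], reference_id: str
) -> ConservationProfile:
    """Column conservation of an MSA mapped onto reference residue numbers.

    Per column the score is ``1 - H / log2(20)`` with ``H`` the Shannon
    entropy of the non-gap residues.  Columns where the reference has a gap
    are skipped; columns gapped in every non-reference row are flagged
    ``no_data``.  The result is invariant to MSA row order.
    """
    by_id = {r.id: r for r in msa}
    if reference_id not in by_id:
        raise ValueError(f"reference '{reference_id}' absent from MSA")
    ref = by_id[reference_id]
    ncol = len(ref.sequence)
    for rec in msa:
        if len(rec.sequence) != ncol:
            raise ValueError(
                f"MSA row '{rec.id}' length {len(rec.sequence)} != {ncol}"
            )
    others = [r for r in msa if r.id != reference_id]

    numbers, scores, nodata = [], [], []
    resnum = ref.start_residue - 1
    max_entropy = np.log2(20.0)
    for col in range(ncol):
        if ref.sequence[col] == "-":
            continue
        resnum += 1
        residues = [
            r.sequence[col] for r in msa if r.sequence[col] != "-"
        ]
        others_empty = all(r.sequence[col] == "-" for r in others)
        counts = pd.Series(residues).value_counts().to_numpy(dtype=float)
        freqs = counts / counts.sum()
        entropy = float(-(freqs * np.log2(freqs)).sum())
        numbers.append(resnum)
        scores.append(1.0 - entropy / max_entropy)
        nodata.append(others_empty)
    return ConservationProfile(
        reference_id=reference_id,
        residue_numbers=np.array(numbers, dtype=int),
        scores=np.array(scores, dtype=float),
        no_data=np.array(nodata, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Structure annotations and the verdict
# ---------------------------------------------------------------------------

SS_STATES = frozenset("HECU")


@dataclass
class ResidueAnnotation:
    """Per-residue structure annotation tracks aligned to a sequence.

    ``ss`` is a string over {H, E, C, U} (U = unknown); ``rsasa`` in [0, 1]
    and ``plddt`` in [0, 100] are optional tracks of the same length.
    """

    protein_id: str
    ss: str
    rsasa: Optional[np.ndarray] = None
    plddt: Optional[np.ndarray] = None
    start_residue: int = 1

    def __post_init__(self) -> None:
        bad = set(self.ss) - SS_STATES
        if bad:
            raise ValueError(f"invalid secondary-structure states {bad}")
        for name, track, lo, hi in (
            ("rsasa", self.rsasa, 0.0, 1.0),
            ("plddt", self.plddt, 0.0, 100.0),
        ):
            if track is None:
                continue
            track = np.asarray(track, dtype=float)
            if len(track) != len(self.ss):
                raise ValueError(
                    f"{name} length {len(track)} != ss length {len(self.ss)}"
                )
            if np.nanmin(track) < lo or np.nanmax(track) > hi:
                raise ValueError(f"{name} values outside [{lo}, {hi}]")
            setattr(self, name, track)

    @property
    def end_residue(self) -> int:
        return self.start_residue + len(self.ss) - 1

    def _slice(self, start: int, end: int) -> slice:
        if start < self.start_residue or end > self.end_residue:
            raise ValueError(
                f"span {start}-{end} outside annotation of '{self.protein_id}' "
                f"[{self.start_residue}, {self.end_residue}]"
            )
        return slice(start - self.start_residue, end - self.start_residue + 1)


@dataclass(frozen=True)
class ContextThresholds:
    """Configurable cutoffs for the three candidate criteria.

    Defaults: pLDDT >= 70 marks a confidently structured residue, mean rSASA
    >= 0.25 marks an exposed motif, mean anchor-column conservation >= 0.5
    marks a conserved motif, and more than half of hit residues must be
    confidently structured to reject a motif as inaccessible.
    """

    plddt_min: float = 70.0
    rsasa_min: float = 0.25
    cons_min: float = 0.5


@dataclass
class ContextVerdict:
    """Pass/fail verdict for one motif hit with per-criterion flags.

    Flags are True/False when evidence was available, None otherwise.
    ``overall`` is "pass" iff no ``fail_*`` reason is present.
    """

    hit: MotifHit
    conserved: Optional[bool]
    flexible: Optional[bool]
    exposed: Optional[bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def overall(self) -> str:
        return "fail" if any(r.startswith("fail_") for r in self.reasons) else "pass"


def classify_context(
    hit: MotifHit,
    annotation: Optional[ResidueAnnotation] = None,
    conservation: Optional[ConservationProfile] = None,
    thresholds: ContextThresholds = ContextThresholds(),
) -> ContextVerdict:
    """Apply the three candidate criteria to a motif hit.

    * ``fail_structured``: more than half of hit residues are H/E and
      confidently structured (pLDDT >= ``plddt_min`` where pLDDT is present).
    * ``fail_buried``: rSASA is available and its mean over the hit is below
      ``rsasa_min``.
    * ``fail_nonconserved``: conservation is available and the mean
      anchor-column score is below ``cons_min``.

    Missing tracks yield ``no_data`` notes, never failures.
    """
    reasons: list[str] = []
    flexible: Optional[bool] = None
    exposed: Optional[bool] = None
    conserved: Optional[bool] = None

    if annotation is not None:
        span = annotation._slice(hit.start, hit.end)
        ss = np.frombuffer(annotation.ss[span].encode(), dtype="S1")
        structured = np.isin(ss, [b"H", b"E"])
        if annotation.plddt is not None:
            structured &= annotation.plddt[span] >= thresholds.plddt_min
        n_res = hit.end - hit.start + 1
        is_structured = structured.sum() > n_res / 2
        flexible = not is_structured
        if is_structured:
            reasons.append("fail_structured")
        if annotation.rsasa is not None:
            mean_rsasa = float(np.mean(annotation.rsasa[span]))
            exposed = mean_rsasa >= thresholds.rsasa_min
            if not exposed:
                reasons.append("fail_buried")
        else:
            reasons.append("no_data")
    else:
        reasons.append("no_data")

    if conservation is not None:
        anchor_scores = [
            conservation.score_at(hit.anchor1_residue),
            conservation.score_at(hit.anchor2_residue),
        ]
        available = [s for s in anchor_scores if s is not None]
        if available:
            conserved = float(np.mean(available)) >= thresholds.cons_min
            if not conserved:
                reasons.append("fail_nonconserved")
        else:
            reasons.append("no_data")
    else:
        reasons.append("no_data")

    return ContextVerdict(
        hit=hit, conserved=conserved, flexible=flexible, exposed=exposed,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_annotations(
    annotations: Mapping[str, ResidueAnnotation],
    target: Union[str, Path, IO[str]],
) -> None:
    """Write annotations as TSV (protein_id, residue, ss, rsasa, plddt)."""
    rows = []
    for ann in annotations.values():
        for i, ss in enumerate(ann.ss):
            rows.append(
                {
                    "protein_id": ann.protein_id,
                    "residue": ann.start_residue + i,
                    "ss": ss,
                    "rsasa": None if ann.rsasa is None else ann.rsasa[i],
                    "plddt": None if ann.plddt is None else ann.plddt[i],
                }
            )
    pd.DataFrame(rows).to_csv(target, sep="\t", index=False, float_format="%.4f")


def read_annotations(
    source: Union[str, Path, IO[str]]
) -> dict[str, ResidueAnnotation]:
    frame = pd.read_csv(source, sep="\t", comment="#")
    out: dict[str, ResidueAnnotation] = {}
    for pid, sub in frame.groupby("protein_id", sort=False):
        sub = sub.sort_values("residue")
        rsasa = sub["rsasa"].to_numpy(dtype=float) if "rsasa" in sub else None
        plddt = sub["plddt"].to_numpy(dtype=float) if "plddt" in sub else None
        if rsasa is not None and np.all(np.isnan(rsasa)):
            rsasa = None
        if plddt is not None and np.all(np.isnan(plddt)):
            plddt = None
        out[str(pid)] = ResidueAnnotation(
            protein_id=str(pid),
            ss="".join(sub["ss"]),
            rsasa=rsasa,
            plddt=plddt,
            start_residue=int(sub["residue"].iloc[0]),
        )
    return out


def verdicts_to_frame(verdicts: Sequence[ContextVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "protein_id": v.hit.protein_id,
                "start": v.hit.start,
                "end": v.hit.end,
                "pattern": v.hit.pattern_name,
                "conserved": v.conserved,
                "flexible": v.flexible,
                "exposed": v.exposed,
                "overall": v.overall,
                "reasons": ";".join(v.reasons) or ".",
            }
        )
    return pd.DataFrame(rows)
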
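"""Seeded generators for every input the pipeline consumes, with truth tables.

Each generator takes a single integer seed and is byte-identical on
regeneration (one ``numpy.random.default_rng(seed)`` stream per generator;
draws occur in a fixed order).  The generators emulate:

* a small proteome of structured blocks and disordered linkers, with TBM
  instances implanted in linkers and sequence decoys buried in structured
  blocks (the context filter should accept the former and reject the latter),
* multiple sequence alignments with tunable column conservation,
* single-site titration isotherms at published syringe/cell concentrations,
* a toy peptide-receptor complex with constructed hydrogen bonds and one
  salt bridge at prescribed distances,
* log-normal intensity matrices with left-censored missingness and spiked-in
  group effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .context import ResidueAnnotation
from .fasta import ProteinRecord
from .itc import BindingParams, Isotherm, TitrationProtocol, simulate_isotherm
from .structure import Atom, StructureModel, write_pdb

# Compositional biases from standard disorder-propensity groupings:
# disorder-promoting residues dominate linkers, order-promoting (hydrophobic)
# residues dominate structured blocks.
LINKER_RESIDUES = "DESTPGNQKA"
LINKER_WEIGHTS = np.array([2, 3, 3, 2, 2, 2, 1, 1, 2, 1], dtype=float)
STRUCTURED_RESIDUES = "ILVFMWYACGTHRNK"
STRUCTURED_WEIGHTS = np.array(
    [3, 3, 3, 2, 1, 1, 2, 2, 1, 1, 1, 1, 1, 1, 1], dtype=float
)


def _choice(rng: np.random.Generator, alphabet: str, weights: np.ndarray,
            size: int) -> str:
    probs = weights / weights.sum()
    return "".join(rng.choice(list(alphabet), size=size, p=probs))


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    annotations: dict[str, ResidueAnnotation]
    truth: pd.DataFrame  # protein_id, start, end, kind, pattern, sequence


def _motif_instance(rng: np.random.Generator, relaxed: bool) -> str:
    x1 = _choice(rng, LINKER_RESIDUES, LINKER_WEIGHTS, 1)
    x2 = _choice(rng, LINKER_RESIDUES, LINKER_WEIGHTS, 1)
    small = "GA"[rng.integers(0, 2)]
    if relaxed:
        # glutamine first anchor and non-alanine position 6
        tail = "TSQ"[rng.integers(0, 3)]
        return "Q" + x1 + small + x2 + "E" + tail
    return "E" + x1 + small + x2 + "EA"


def make_synthetic_proteome(
    n_proteins: int = 60,
    n_implants: int = 25,
    seed: Optional[int] = None,
    n_decoys: Optional[int] = None,
    relaxed_fraction: float = 0.2,
) -> SyntheticProteome:
    """Proteome of structured blocks and linkers with implants and decoys.

    Structured blocks are hydrophobic-biased, annotated H or E with high
    pLDDT and low rSASA; linkers are disorder-biased, annotated C with low
    pLDDT and high rSASA.  ``n_implants`` motif instances are placed inside
    linkers (a ``relaxed_fraction`` of them as the glutamine-anchored relaxed
    variant); ``n_decoys`` (default: ``n_implants``) motif-matching strings
    are placed inside structured blocks, keeping structured annotations, so
    the context filter should reject them.
    """
    if n_decoys is None:
        n_decoys = n_implants
    if n_implants > n_proteins or n_decoys > n_proteins:
        raise ValueError("cannot implant more motifs than proteins")
    rng = np.random.default_rng(seed)

    records: list[ProteinRecord] = []
    annotations: dict[str, ResidueAnnotation] = {}
    segments_by_protein: list[list[tuple[str, int, int]]] = []
    for p in range(n_proteins):
        parts: list[str] = []
        ss_parts: list[str] = []
        rsasa_parts: list[np.ndarray] = []
        plddt_parts: list[np.ndarray] = []
        segments: list[tuple[str, int, int]] = []  # (kind, start0, end0)
        pos = 0
        n_blocks = int(rng.integers(2, 4))  # structured blocks per protein
        for b in range(n_blocks):
            s_len = int(rng.integers(30, 61))
            ss_state = "H" if rng.random() < 0.5 else "E"
            parts.append(
                _choice(rng, STRUCTURED_RESIDUES, STRUCTURED_WEIGHTS, s_len)
            )
            ss_parts.append(ss_state * s_len)
            rsasa_parts.append(rng.uniform(0.0, 0.2, s_len))
            plddt_parts.append(np.clip(rng.normal(92, 3, s_len), 0, 100))
            segments.append(("structured", pos, pos + s_len - 1))
            pos += s_len
            l_len = int(rng.integers(20, 41))
            parts.append(_choice(rng, LINKER_RESIDUES, LINKER_WEIGHTS, l_len))
            ss_parts.append("C" * l_len)
            rsasa_parts.append(rng.uniform(0.35, 0.9, l_len))
            plddt_parts.append(np.clip(rng.normal(45, 8, l_len), 0, 100))
            segments.append(("linker", pos, pos + l_len - 1))
            pos += l_len
        pid = f"synprot{p:04d}"
        records.append(ProteinRecord(id=pid, sequence="".join(parts)))
        annotations[pid] = ResidueAnnotation(
            protein_id=pid,
            ss="".join(ss_parts),
            rsasa=np.concatenate(rsasa_parts),
            plddt=np.concatenate(plddt_parts),
        )
        segments_by_protein.append(segments)

    truth_rows: list[dict] = []

    def implant(protein_idx: int, kind: str) -> None:
        nonlocal records
        rec = records[protein_idx]
        segments = segments_by_protein[protein_idx]
        want = "linker" if kind == "implant" else "structured"
        candidates = [s for s in segments if s[0] == want]
        seg = candidates[rng.integers(0, len(candidates))]
        relaxed = kind == "implant" and rng.random() < relaxed_fraction
        motif = _motif_instance(rng, relaxed)
        lo, hi = seg[1] + 3, seg[2] - 3 - len(motif) + 1
        if hi <= lo:
            lo, hi = seg[1], seg[2] - len(motif) + 1
        start0 = int(rng.integers(lo, hi + 1))
        seq = rec.sequence
        new_seq = seq[:start0] + motif + seq[start0 + len(motif):]
        records[protein_idx] = ProteinRecord(
            id=rec.id, sequence=new_seq, description=rec.description,
            start_residue=rec.start_residue,
        )
        truth_rows.append(
            {
                "protein_id": rec.id,
                "start": start0 + 1,
                "end": start0 + len(motif),
                "kind": kind,
                "pattern": "relaxed" if relaxed else "strict",
                "sequence": motif,
            }
        )

    implant_proteins = rng.choice(n_proteins, size=n_implants, replace=False)
    for idx in implant_proteins:
        implant(int(idx), "implant")
    decoy_proteins = rng.choice(n_proteins, size=n_decoys, replace=False)
    for idx in decoy_proteins:
        implant(int(idx), "decoy")

    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "start", "end", "kind", "pattern", "sequence"],
    )
    return SyntheticProteome(records=records, annotations=annotations,
                             truth=truth)


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

def make_synthetic_msa(
    reference: ProteinRecord,
    anchor_conservation: float = 0.95,
    background_conservation: float = 0.5,
    n_seqs: int = 20,
    seed: Optional[int] = None,
    anchor_columns: Sequence[int] = (),
    gap_rate: float = 0.02,
) -> list[ProteinRecord]:
    """Alignment rows mutated independently from a reference sequence.

    ``anchor_columns`` are 0-based column indices kept at
    ``anchor_conservation``; all other columns mutate at rate
    ``1 - background_conservation``.  Row 1 is the unmutated reference.
    Gaps are inserted at ``gap_rate`` in non-reference rows.
    """
    for v in (anchor_conservation, background_conservation):
        if not 0.0 <= v <= 1.0:
            raise ValueError("conservation parameters must be in [0, 1]")
    rng = np.random.default_rng(seed)
    anchors = set(anchor_columns)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = [reference]
    for i in range(1, n_seqs):
        chars = []
        for col, ch in enumerate(reference.sequence):
            keep = anchor_conservation if col in anchors else background_conservation
            if rng.random() < gap_rate:
                chars.append("-")
            elif rng.random() < keep:
                chars.append(ch)
            else:
                chars.append(aa[rng.integers(0, 20)])
        rows.append(
            ProteinRecord(id=f"{reference.id}_hom{i:03d}",
                          sequence="".join(chars))
        )
    return rows


# ---------------------------------------------------------------------------
# Isotherms
# ---------------------------------------------------------------------------

#: Published titration conditions (syringe -> cell, molar) and generating
#: single-site parameters, one preset per interactor (run i of each series).
ISOTHERM_PRESETS: dict[str, dict] = {
    "RILPL1_i": {"syringe": 0.45e-3, "cell": 0.06e-3, "kd": 590e-9,
                 "dh": -12.1, "n": 0.95},
    "OCRL-PH_i": {"syringe": 0.30e-3, "cell": 0.015e-3, "kd": 1700e-9,
                  "dh": -5.3, "n": 0.69},
    "WDR81_i": {"syringe": 0.30e-3, "cell": 0.04e-3, "kd": 20e-9,
                "dh": -9.0, "n": 0.94},
    "JIP3_i": {"syringe": 0.30e-3, "cell": 0.03e-3, "kd": 127e-9,
               "dh": -8.2, "n": 1.2},
    "JIP4_i": {"syringe": 0.40e-3, "cell": 0.03e-3, "kd": 2900e-9,
               "dh": -8.9, "n": 1.0},
}


def make_synthetic_isotherm(
    preset: str = "RILPL1_i",
    params: Optional[BindingParams] = None,
    protocol: Optional[TitrationProtocol] = None,
    noise_sd: float = 0.1,
    seed: Optional[int] = None,
) -> tuple[Isotherm, TitrationProtocol, BindingParams]:
    """Simulated isotherm plus the protocol and generating (truth) parameters.

    Defaults to the published concentration presets with a 19 x 2 uL
    injection scheme into a 200 uL cell and 0.1 kcal/mol Gaussian heat noise.
    """
    if params is None or protocol is None:
        spec = ISOTHERM_PRESETS[preset]
        if protocol is None:
            protocol = TitrationProtocol.uniform(
                syringe_conc=spec["syringe"], cell_conc=spec["cell"]
            )
        if params is None:
            params = BindingParams(n=spec["n"], kd=spec["kd"], dh=spec["dh"])
    iso = simulate_isotherm(params, protocol, noise_sd=noise_sd, seed=seed)
    return iso, protocol, params


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    pdb_text: str
    model: StructureModel
    truth: pd.DataFrame  # kind, donor/acidic atom, acceptor/basic atom, distance


def _bb_residue(
    atoms: list[Atom], serial: int, chain: str, resnum: int, resname: str,
    origin: np.ndarray,
) -> int:
    """Append a minimal backbone (N, CA, C, O) residue; returns next serial."""
    offsets = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.2, 0.9, 0.0]),
        "C": np.array([2.4, 0.0, 0.0]),
        "O": np.array([2.4, -1.23, 0.0]),
    }
    for name, off in offsets.items():
        atoms.append(
            Atom(
                serial=serial, name=name, element=name[0],
                residue_name=resname, residue_number=resnum,
                insertion_code="", chain_id=chain,
                xyz=tuple(np.round(origin + off, 3)),
            )
        )
        serial += 1
    return serial


def make_toy_complex(seed: Optional[int] = None) -> ToyComplex:
    """A 6-residue extended peptide against a minimal receptor groove.

    Constructs three peptide-backbone-N to receptor-backbone-O hydrogen
    bonds at prescribed distances in [2.8, 3.2] A, one Glu-Arg salt bridge
    at 3.0 +/- 0.2 A, and one non-contact control residue pair > 6 A away.
    The truth table lists every intended contact; the generator verifies
    that no unintended backbone donor-acceptor or acid-base pair falls
    within the default cutoffs (3.5 / 4.0 A) plus a 0.3 A margin.  Note the
    salt-bridge pair necessarily also registers as a sidechain N-O contact,
    so backbone hydrogen-bond truths are recovered with
    ``find_hbonds(..., backbone_only=True)``.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    spacing = 7.0
    peptide_seq = ["GLU", "GLN", "GLY", "GLN", "GLU", "ALA"]
    pep_origin = {}
    for i, resname in enumerate(peptide_seq):
        origin = np.array([i * spacing, 0.0, 0.0])
        pep_origin[i + 1] = origin
        serial = _bb_residue(atoms, serial, "P", 391 + i, resname, origin)

    # peptide GLU 5 sidechain pointing +y (OE1/OE2 on residue 395)
    glu_origin = pep_origin[5]
    oe1 = glu_origin + np.array([1.2, 3.2, 0.0])
    for name, off in (
        ("CB", np.array([1.2, 1.9, 0.6])),
        ("CG", np.array([1.2, 2.6, 1.2])),
        ("CD", np.array([1.2, 3.1, 0.9])),
        ("OE1", oe1 - glu_origin),
        # OE2 points away from the arginine so only OE1 is in bridge range
        ("OE2", (oe1 - glu_origin) + np.array([0.0, -2.2, 0.0])),
    ):
        atoms.append(
            Atom(serial=serial, name=name, element=name[0],
                 residue_name="GLU", residue_number=395, insertion_code="",
                 chain_id="P", xyz=tuple(np.round(glu_origin + off, 3)))
        )
        serial += 1

    truth_rows: list[dict] = []
    # receptor backbone oxygens below peptide N of residues 1, 3, 6
    hb_targets = [1, 3, 6]
    for j, pep_res in enumerate(hb_targets):
        d = float(rng.uniform(2.8, 3.2))
        pep_n = pep_origin[pep_res]  # N at the residue origin
        # receptor O lands exactly d below the peptide N
        origin = pep_n + np.array([-2.4, -d, 0.0])
        resnum = 140 + j
        offsets = {
            "O": np.array([2.4, 0.0, 0.0]),
            "C": np.array([2.4, -1.23, 0.0]),
            "CA": np.array([1.2, -2.1, 0.0]),
            "N": np.array([0.0, -2.9, 0.0]),
        }
        for name, off in offsets.items():
            atoms.append(
                Atom(serial=serial, name=name, element=name[0],
                     residue_name="GLY", residue_number=resnum,
                     insertion_code="", chain_id="T",
                     xyz=tuple(np.round(origin + off, 3)))
            )
            serial += 1
        truth_rows.append(
            {
                "kind": "hbond",
                "chain_a": "P", "res_a": 390 + pep_res, "atom_a": "N",
                "chain_b": "T", "res_b": resnum, "atom_b": "O",
                "distance": float(np.linalg.norm(
                    np.round(pep_n, 3) - np.round(origin + offsets["O"], 3))),
            }
        )

    # receptor arginine: NH1 at 3.0 +/- 0.2 A above peptide OE1
    d_sb = float(rng.uniform(2.8, 3.2))
    nh1 = oe1 + np.array([0.0, d_sb, 0.0])
    arg_atoms = {
        "NH1": nh1,
        "CZ": nh1 + np.array([0.0, 1.33, 0.0]),
        "NH2": nh1 + np.array([1.15, 2.0, 0.0]),
        "NE": nh1 + np.array([-1.15, 2.0, 0.0]),
        "CA": nh1 + np.array([0.0, 3.8, 0.0]),
        "N": nh1 + np.array([-1.0, 4.6, 0.0]),
        "C": nh1 + np.array([1.2, 4.4, 0.0]),
        "O": nh1 + np.array([1.4, 5.6, 0.0]),
    }
    for name, pos in arg_atoms.items():
        atoms.append(
            Atom(serial=serial, name=name, element=name[0],
                 residue_name="ARG", residue_number=151, insertion_code="",
                 chain_id="T", xyz=tuple(np.round(pos, 3)))
        )
        serial += 1
    truth_rows.append(
        {
            "kind": "salt_bridge",
            "chain_a": "P", "res_a": 395, "atom_a": "OE1",
            "chain_b": "T", "res_b": 151, "atom_b": "NH1",
            "distance": round(float(np.linalg.norm(
                np.round(oe1, 3) - np.round(nh1, 3))), 3),
        }
    )

    # control: receptor lysine far from everything (> 6 A)
    far = np.array([-15.0, -15.0, 8.0])
    for name, off in (
        ("N", np.array([0.0, 0.0, 0.0])),
        ("CA", np.array([1.2, 0.9, 0.0])),
        ("NZ", np.array([2.0, 2.0, 1.0])),
    ):
        atoms.append(
            Atom(serial=serial, name=name, element=name[0],
                 residue_name="LYS", residue_number=200, insertion_code="",
                 chain_id="T", xyz=tuple(np.round(far + off, 3)))
        )
        serial += 1
    truth_rows.append(
        {
            "kind": "control_noncontact",
            "chain_a": "P", "res_a": 395, "atom_a": "OE1",
            "chain_b": "T", "res_b": 200, "atom_b": "NZ",
            "distance": round(float(np.linalg.norm(
                np.round(oe1, 3) - np.round(far + np.array([2.0, 2.0, 1.0]), 3))), 3),
        }
    )

    model = StructureModel(atoms=atoms, source_id="toy_complex")
    truth = pd.DataFrame(truth_rows)
    _verify_toy_margins(model, truth)
    return ToyComplex(pdb_text=write_pdb(model), model=model, truth=truth)


def _verify_toy_margins(model: StructureModel, truth: pd.DataFrame) -> None:
    """Assert that only intended contacts fall near the default cutoffs."""
    from .structure import find_hbonds, find_salt_bridges

    intended_hb = {
        (r.res_a, r.atom_a, r.res_b, r.atom_b)
        for r in truth.itertuples() if r.kind == "hbond"
    }
    for hb in find_hbonds(model, "P", "T", d_max=3.8, backbone_only=True):
        key = (hb.donor.residue_number, hb.donor.name,
               hb.acceptor.residue_number, hb.acceptor.name)
        if key not in intended_hb:
            raise AssertionError(f"unintended donor-acceptor pair {key}")
    intended_sb = {
        (r.res_a, r.atom_a, r.res_b, r.atom_b)
        for r in truth.itertuples() if r.kind == "salt_bridge"
    }
    for sb in find_salt_bridges(model, "P", "T", d_max=4.3):
        key = (sb.acidic.residue_number, sb.acidic.name,
               sb.basic.residue_number, sb.basic.name)
        if key not in intended_sb:
            raise AssertionError(f"unintended acid-base pair {key}")


# ---------------------------------------------------------------------------
# Intensity matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticIntensities:
    matrix: pd.DataFrame
    groups: dict[str, str]
    truth: pd.DataFrame  # protein_id, spiked, effect_log2


def make_synthetic_intensities(
    n_proteins: int = 500,
    n_per_group: int = 4,
    n_spiked: int = 25,
    effect_log2: float = 2.0,
    missing_rate: float = 0.1,
    seed: Optional[int] = None,
    within_sd: float = 0.5,
) -> SyntheticIntensities:
    """Log-normal intensity matrix with spike-ins and left-censored holes.

    Baseline log2 intensities are protein-level means drawn from
    ``Normal(25, 2)`` plus within-group noise ``Normal(0, within_sd)``;
    spiked rows gain ``effect_log2`` in group 2.  Missingness is
    left-censored: the probability of a hole falls logistically with the
    (noisy) true intensity, calibrated so the overall rate is about
    ``missing_rate``.
    """
    if n_spiked > n_proteins:
        raise ValueError("n_spiked > n_proteins")
    rng = np.random.default_rng(seed)
    base = rng.normal(25.0, 2.0, n_proteins)
    n_samples = 2 * n_per_group
    values = base[:, None] + rng.normal(0.0, within_sd, (n_proteins, n_samples))
    spiked_idx = rng.choice(n_proteins, size=n_spiked, replace=False)
    values[spiked_idx, n_per_group:] += effect_log2

    if missing_rate > 0:
        threshold = np.quantile(values, missing_rate)
        p_missing = 1.0 / (1.0 + np.exp((values - threshold) / 0.5))
        scale = missing_rate / max(p_missing.mean(), 1e-12)
        holes = rng.random(values.shape) < np.clip(p_missing * scale, 0, 1)
        # keep at least 2 observed values per column for imputation
        for j in range(n_samples):
            observed = ~holes[:, j]
            if observed.sum() < 2:
                holes[: 2, j] = False
        values = np.where(holes, np.nan, values)

    ids = [f"prot{i:04d}" for i in range(n_proteins)]
    samples = [f"ctrl_{k+1}" for k in range(n_per_group)] + [
        f"case_{k+1}" for k in range(n_per_group)
    ]
    groups = {s: ("ctrl" if s.startswith("ctrl") else "case") for s in samples}
    matrix = pd.DataFrame(values, index=ids, columns=samples)
    spiked = np.zeros(n_proteins, dtype=bool)
    spiked[spiked_idx] = True
    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "spiked": spiked,
            "effect_log2": np.where(spiked, effect_log2, 0.0),
        }
    )
    return SyntheticIntensities(matrix=matrix, groups=groups, truth=truth)
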
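"""Peptide-receptor interface geometry from coordinate files.

PDB parsing and writing are delegated to gemmi; author residue numbering is
preserved as the public coordinate system so contacts line up with
mutagenesis labels (e.g. the E398-R151 salt bridge).  Contact detection uses
hydrogen-free donor-acceptor distance criteria, appropriate for crystal
structures deposited without hydrogens; Kabsch superposition is computed via
SVD with reflection correction.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

BACKBONE_DONOR = "N"
BACKBONE_ACCEPTORS = ("O", "OXT")
#: Sidechain carboxylate oxygens of acidic residues.
ACIDIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
#: Basic nitrogens; histidine excluded by default (protonation unknown).
BASIC_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
HIS_BASIC_ATOMS = {"HIS": ("ND1", "NE2")}


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column coordinate records."""


@dataclass(frozen=True)
class Atom:
    """One atom with author numbering; ``bfactor`` carries pLDDT for
    predicted models."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    xyz: tuple[float, float, float]
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def distance_to(self, other: "Atom") -> float:
        return math.dist(self.xyz, other.xyz)


@dataclass
class StructureModel:
    """Ordered atoms with a chain/residue lookup."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name,
                   a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def select(
        self,
        chain: Optional[str] = None,
        residues: Optional[Iterable[int]] = None,
        atom_names: Optional[Iterable[str]] = None,
    ) -> list[Atom]:
        residues = None if residues is None else set(residues)
        atom_names = None if atom_names is None else set(atom_names)
        return [
            a
            for a in self.atoms
            if (chain is None or a.chain_id == chain)
            and (residues is None or a.residue_number in residues)
            and (atom_names is None or a.name in atom_names)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy of the model with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        atoms = []
        for a in self.atoms:
            xyz = rotation @ np.asarray(a.xyz) + translation
            atoms.append(
                Atom(
                    serial=a.serial, name=a.name, element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    insertion_code=a.insertion_code, chain_id=a.chain_id,
                    xyz=tuple(float(v) for v in xyz), bfactor=a.bfactor,
                    occupancy=a.occupancy, altloc=a.altloc,
                )
            )
        return StructureModel(atoms=atoms, source_id=self.source_id)


def _precheck_pdb(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBFormatError(
                    f"line {lineno}: ATOM/HETATM record shorter than 54 columns"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: malformed coordinate fields"
                ) from None


def read_pdb(source: Union[str, Path, IO[str]], source_id: str = "") -> StructureModel:
    """Parse fixed-column PDB text (path, text, or handle).

    Only the first MODEL is kept; altloc policy keeps blank or 'A'
    conformers.  Author residue numbering is preserved.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        s = str(source)
        text = s if "\n" in s else Path(s).read_text()
    _precheck_pdb(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(str(exc)) from exc
    if len(st) == 0:
        return StructureModel(atoms=[], source_id=source_id or st.name)
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        bfactor=atom.b_iso,
                        occupancy=atom.occ,
                        altloc="" if atom.altloc in ("", "\0") else atom.altloc,
                    )
                )
    return StructureModel(atoms=atoms, source_id=source_id or st.name)


def write_pdb(model: StructureModel) -> str:
    """Render a model as PDB text (inverse of :func:`read_pdb`)."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        key = a.residue_key
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            chains[a.chain_id].add_residue(res)
            residues[key] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        atom.b_iso = a.bfactor
        atom.occ = a.occupancy
        atom.serial = a.serial
        if a.altloc:
            atom.altloc = a.altloc
        residues[key].add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))


def plddt_profile(model: StructureModel, chain: str) -> dict[int, float]:
    """Per-residue pLDDT read from the B-factor column (CA atom convention)."""
    out: dict[int, float] = {}
    for atom in model.select(chain=chain, atom_names=["CA"]):
        out[atom.residue_number] = atom.bfactor
    return out


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    """Donor(N)-acceptor(O) pair within the distance cutoff."""

    donor: Atom
    acceptor: Atom
    distance: float
    kind: str  # backbone | sidechain | mixed


@dataclass(frozen=True)
class SaltBridge:
    """Acidic carboxylate oxygen paired with a basic nitrogen."""

    acidic: Atom
    basic: Atom
    distance: float


Selection = Union[str, Sequence[Atom]]


def _resolve(model: StructureModel, selection: Selection) -> list[Atom]:
    if isinstance(selection, str):
        atoms = model.select(chain=selection)
        if not atoms:
            raise ValueError(f"chain '{selection}' not found or empty")
        return atoms
    atoms = list(selection)
    if not atoms:
        raise ValueError("empty atom selection")
    return atoms


def _is_backbone(atom: Atom) -> bool:
    return atom.name in ("N", "CA", "C", "O", "OXT")


def find_hbonds(
    model: StructureModel,
    selection_a: Selection,
    selection_b: Selection,
    d_max: float = 3.5,
    backbone_only: bool = False,
) -> list[HBond]:
    """All N(-type) -> O(-type) pairs across two selections within ``d_max``.

    Distance criterion only (no hydrogens or angles required).  Donors are
    nitrogen atoms, acceptors oxygen atoms; both directions across the two
    selections are scanned.  Results sorted by distance.
    """
    a = _resolve(model, selection_a)
    b = _resolve(model, selection_b)
    bonds: list[HBond] = []
    for donors, acceptors in ((a, b), (b, a)):
        for donor in donors:
            if donor.element != "N":
                continue
            if backbone_only and donor.name != BACKBONE_DONOR:
                continue
            for acceptor in acceptors:
                if acceptor.element != "O":
                    continue
                if backbone_only and acceptor.name not in BACKBONE_ACCEPTORS:
                    continue
                d = donor.distance_to(acceptor)
                if d <= d_max:
                    donor_bb = donor.name == BACKBONE_DONOR
                    acceptor_bb = acceptor.name in BACKBONE_ACCEPTORS
                    kind = (
                        "backbone" if donor_bb and acceptor_bb
                        else "sidechain" if not donor_bb and not acceptor_bb
                        else "mixed"
                    )
                    bonds.append(HBond(donor, acceptor, d, kind))
    return sorted(bonds, key=lambda hb: hb.distance)


def find_salt_bridges(
    model: StructureModel,
    selection_a: Selection,
    selection_b: Selection,
    d_max: float = 4.0,
    include_his: bool = False,
) -> list[SaltBridge]:
    """Acidic (Glu/Asp carboxylate O) - basic (Arg/Lys N) pairs within ``d_max``.

    Histidine nitrogens count as basic only when ``include_his`` is set.
    Both directions across the two selections are scanned; sorted by distance.
    """
    a = _resolve(model, selection_a)
    b = _resolve(model, selection_b)
    basic_atoms = dict(BASIC_ATOMS)
    if include_his:
        basic_atoms.update(HIS_BASIC_ATOMS)

    def acidic(atom: Atom) -> bool:
        return atom.name in ACIDIC_ATOMS.get(atom.residue_name, ())

    def basic(atom: Atom) -> bool:
        return atom.name in basic_atoms.get(atom.residue_name, ())

    bridges: list[SaltBridge] = []
    for side_a, side_b in ((a, b), (b, a)):
        for acid in side_a:
            if not acidic(acid):
                continue
            for base in side_b:
                if not basic(base):
                    continue
                d = acid.distance_to(base)
                if d <= d_max:
                    bridges.append(SaltBridge(acid, base, d))
    return sorted(bridges, key=lambda sb: sb.distance)


def interface_residues(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Residue pairs across two chains with any-atom minimum distance <= cutoff.

    Returns ``(residue_a, residue_b, min_distance)`` triples, each residue a
    ``(chain, number, insertion_code)`` key, each pair reported once, sorted
    by distance.
    """
    atoms_a = _resolve(model, chain_a)
    atoms_b = _resolve(model, chain_b)
    xyz_a = np.array([a.xyz for a in atoms_a])
    xyz_b = np.array([b.xyz for b in atoms_b])
    dist = cdist(xyz_a, xyz_b)
    best: dict[tuple, float] = {}
    for i, a in enumerate(atoms_a):
        for j, b in enumerate(atoms_b):
            d = dist[i, j]
            if d <= cutoff:
                key = (a.residue_key, b.residue_key)
                if d < best.get(key, math.inf):
                    best[key] = d
    return sorted(
        [(ka, kb, d) for (ka, kb), d in best.items()], key=lambda t: t[2]
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform minimizing RMSD of paired points A onto B."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Kabsch least-squares superposition of paired point sets A onto B.

    Centroid shift plus SVD rotation with determinant correction, so the
    returned rotation is always proper (no reflections).  Requires at least
    3 non-collinear point pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coords must be matching (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("points are collinear; rotation underdetermined")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cb - rotation @ ca
    moved = a @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return Superposition(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def superpose_ca(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
) -> Superposition:
    """Superpose two chains on CA atoms of their shared residue numbers."""
    ca_a = {a.residue_number: a for a in model_a.select(chain=chain_a, atom_names=["CA"])}
    ca_b = {a.residue_number: a for a in model_b.select(chain=chain_b, atom_names=["CA"])}
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError("fewer than 3 shared CA residues")
    coords_a = np.array([ca_a[r].xyz for r in common])
    coords_b = np.array([ca_b[r].xyz for r in common])
    return superpose(coords_a, coords_b)
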
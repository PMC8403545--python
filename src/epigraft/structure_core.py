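"""Structure data model, PDB I/O and geometric primitives.

The in-memory model is deliberately minimal: a :class:`ChainStructure` is an
ordered list of residues carrying author numbering exactly as printed in the
source file, because every range in the grafting protocol (motif 420–429,
graft window 164–173, ...) is expressed in author numbers. Parsing is backed
by gemmi; writing emits fixed-column PDB v3.3 records with 3-decimal
coordinates.

Geometry: optimal rigid superposition (Kabsch, proper rotations only, via
scipy), backbone coordinate extraction, mass-weighted radius of gyration and
Shrake–Rupley solvent-accessible surface area (via biotite) with
Gly-X-Gly-normalized relative values.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .config import DEFAULT_CONFIG

__all__ = [
    "Atom",
    "Residue",
    "ChainStructure",
    "RigidTransform",
    "PDBParseError",
    "PDBWriteError",
    "DegenerateGeometryWarning",
    "parse_pdb",
    "parse_pdb_models",
    "write_pdb",
    "superpose",
    "backbone_coords",
    "residues_backbone_coords",
    "radius_of_gyration",
    "sasa",
    "SasaResult",
    "chains_to_fasta",
    "dihedral",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "MAX_SASA_GXG",
]


# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine reads as methionine
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

#: Theoretical Gly-X-Gly maximum SASA per residue type (Å²), used to turn
#: absolute per-residue SASA into a relative (fractional) exposure.
MAX_SASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "SE": 78.971, "P": 30.974,
}

BACKBONE_ORDER = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be serialized as fixed-column PDB."""


class DegenerateGeometryWarning(UserWarning):
    """Emitted when a superposition target is degenerate (e.g. collinear)."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    from_hetatm: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    name3: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def is_backbone_complete(self, require_o: bool = True) -> bool:
        names = {a.name for a in self.atoms}
        if not {"N", "CA", "C"} <= names:
            return False
        if require_o and not ({"O", "OXT"} & names):
            return False
        return True

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def is_hetero(self) -> bool:
        return all(a.from_hetatm for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.name3} {self.seq_number}{self.insertion_code}"

    def copy(self) -> "Residue":
        return Residue(self.name3, self.seq_number, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class ChainStructure:
    source_id: str           # "<entry>_<chain>", e.g. "1YN3_A"
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def find(self, seq_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def index_of(self, seq_number: int, insertion_code: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return i
        raise KeyError(f"residue {seq_number}{insertion_code} not in {self.source_id}")

    def polymer_residues(self) -> list[Residue]:
        """Residues that carry at least one ATOM (non-HETATM) record, plus MSE."""
        return [r for r in self.residues
                if not r.is_hetero or r.name3 == "MSE"]

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for r in self.residues for a in r.heavy_atoms()]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "ChainStructure":
        return ChainStructure(self.source_id, self.chain_id,
                              [r.copy() for r in self.residues])


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R x + t (rotation then translation)."""

    rotation: np.ndarray   # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflection is not a rigid transform")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------


def _prevalidate_pdb(text: str) -> None:
    """Check fixed-column coordinate records before handing text to gemmi.

    gemmi is lenient about garbage in numeric fields; the contract here is a
    parse error naming the offending line.
    """
    n_coord = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_coord += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field "
                    f"{line[lo:hi]!r}") from None
        occ = line[54:60].strip()
        if occ:
            try:
                float(occ)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed occupancy field {occ!r}") from None
    if n_coord == 0:
        raise PDBParseError("input contains no ATOM or HETATM records")


def _apply_altloc_policy(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc 'A' then
    alphabetical. Order of first appearance is preserved."""
    chosen: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in chosen:
            chosen[atom.name] = atom
            order.append(atom.name)
            continue
        prev = chosen[atom.name]
        key = (-atom.occupancy, atom.altloc != "A", atom.altloc)
        prev_key = (-prev.occupancy, prev.altloc != "A", prev.altloc)
        if key < prev_key:
            chosen[atom.name] = atom
    return [chosen[name] for name in order]


def _convert_model(model: "gemmi.Model", entry_id: str) -> list[ChainStructure]:
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            atoms = []
            for gatom in gres:
                altloc = gatom.altloc if gatom.altloc != "\x00" else ""
                element = gatom.element.name.upper()
                if not element or element == "X":
                    element = gatom.name.strip("0123456789")[:1].upper()
                atoms.append(Atom(
                    serial=gatom.serial,
                    name=gatom.name,
                    element=element,
                    position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=float(gatom.occ),
                    altloc=altloc,
                    from_hetatm=(gres.het_flag == "H"),
                ))
            atoms = _apply_altloc_policy(atoms)
            icode = gres.seqid.icode.strip()
            residues.append(Residue(gres.name, gres.seqid.num, icode, atoms))
        if residues:
            chains.append(ChainStructure(
                source_id=f"{entry_id}_{gchain.name}",
                chain_id=gchain.name,
                residues=residues,
            ))
    return chains


def parse_pdb(text: str, entry_id: str | None = None) -> list[ChainStructure]:
    """Parse PDB-format text into one :class:`ChainStructure` per chain.

    Every ATOM/HETATM record of the first model is represented (waters and
    ligands included, flagged ``from_hetatm``); author numbering, insertion
    codes and file order are preserved. Alternate locations are reduced to a
    single conformer (highest occupancy, ties to altloc 'A').

    Parameters
    ----------
    text:
        PDB-format character stream.
    entry_id:
        Entry identifier for ``source_id``; defaults to the HEADER idCode
        or ``"UNK"``.
    """
    _prevalidate_pdb(text)
    structure = gemmi.read_pdb_string(text)
    entry = entry_id or (structure.name.strip() or "UNK")
    if len(structure) == 0:
        raise PDBParseError("no models in input")
    return _convert_model(structure[0], entry.upper())


def parse_pdb_models(text: str, entry_id: str | None = None) -> list[list[ChainStructure]]:
    """Parse a (possibly multi-MODEL) PDB stream into a list of frames."""
    _prevalidate_pdb(text)
    structure = gemmi.read_pdb_string(text)
    entry = entry_id or (structure.name.strip() or "UNK")
    return [_convert_model(model, entry.upper()) for model in structure]


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBWriteError(f"atom name {name!r} longer than 4 characters")
    if len(name) == 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: ChainStructure | list[ChainStructure]) -> str:
    """Serialize chains as fixed-column PDB v3.3 (ATOM/HETATM, TER, END).

    Coordinates are written to 3 decimals; a parse/write round trip is
    lossless for residue identity, numbering and 3-decimal coordinates.
    """
    chains = [structure] if isinstance(structure, ChainStructure) else list(structure)
    if not chains or all(c.length() == 0 for c in chains):
        raise PDBWriteError("refusing to write an empty structure")
    out = io.StringIO()
    serial = 0
    for chain in chains:
        if chain.length() == 0:
            raise PDBWriteError(f"chain {chain.chain_id} has no residues")
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                if np.any(np.abs(atom.position) >= 10000):
                    raise PDBWriteError(
                        f"coordinate overflow in {res.label} {atom.name}")
                record = "HETATM" if atom.from_hetatm else "ATOM  "
                x, y, z = atom.position
                out.write(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}{res.name3:>3s} {chain.chain_id:1s}"
                    f"{res.seq_number:>4d}{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n")
            last = res
        serial += 1
        out.write(f"TER   {serial:>5d}      {last.name3:>3s} {chain.chain_id:1s}"
                  f"{last.seq_number:>4d}{last.insertion_code or ' '}\n")
    out.write("END\n")
    return out.getvalue()


def chains_to_fasta(chains: ChainStructure | list[ChainStructure]) -> str:
    """FASTA text of the one-letter sequence of each chain."""
    chains = [chains] if isinstance(chains, ChainStructure) else list(chains)
    lines = []
    for chain in chains:
        seq = "".join(r.one_letter for r in chain.polymer_residues())
        lines.append(f">{chain.source_id}")
        lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def superpose(mobile_coords: np.ndarray, target_coords: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rigid transform (reflections excluded) minimizing the
    RMSD of the mobile points onto the target points, and that minimum RMSD
    in Å. Degenerate (e.g. collinear) point sets still yield a least-squares
    optimal fit but raise a :class:`DegenerateGeometryWarning`.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    target = np.asarray(target_coords, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3 or target.shape != mobile.shape:
        raise ValueError("expected two equal-shape (N, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, rssd = Rotation.align_vectors(target - tgt_center, mobile - mob_center)
    for w in caught:
        warnings.warn(f"degenerate point set in superposition: {w.message}",
                      DegenerateGeometryWarning, stacklevel=2)
    rotation = rot.as_matrix()
    translation = tgt_center - rotation @ mob_center
    rmsd = float(rssd) / math.sqrt(n)
    return RigidTransform(rotation, translation), rmsd


# ---------------------------------------------------------------------------
# Coordinate extraction
# ---------------------------------------------------------------------------


def residues_backbone_coords(residues: list[Residue],
                             atom_set: tuple[str, ...] = BACKBONE_ORDER
                             ) -> np.ndarray:
    """Backbone coordinates for a residue list, residue-by-residue in fixed
    N, CA, C, O order (restricted to ``atom_set``)."""
    bad = set(atom_set) - set(BACKBONE_ORDER)
    if bad:
        raise ValueError(f"not backbone atoms: {sorted(bad)}")
    names = [n for n in BACKBONE_ORDER if n in atom_set]
    rows = []
    for res in residues:
        for name in names:
            atom = res.get_atom(name)
            if atom is None and name == "O":
                atom = res.get_atom("OXT")
            if atom is None:
                raise ValueError(f"residue {res.label} lacks backbone atom {name}")
            rows.append(atom.position)
    return np.array(rows, dtype=float).reshape(-1, 3)


def backbone_coords(chain: ChainStructure, start: int, end: int,
                    atom_set: tuple[str, ...] = BACKBONE_ORDER) -> np.ndarray:
    """Backbone coordinates of author-number range [start, end] inclusive."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    residues = []
    for num in range(start, end + 1):
        res = chain.find(num)
        if res is None:
            if any(r.seq_number == num for r in chain.residues):
                raise ValueError(
                    f"residue {num} in {chain.source_id} carries an insertion "
                    "code; ranges must be contiguous in plain author numbers")
            raise ValueError(f"residue {num} missing from {chain.source_id}")
        residues.append(res)
    return residues_backbone_coords(residues, atom_set)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None
                       ) -> float:
    """Mass-weighted RMS distance from the center of mass (Å).

    ``masses=None`` means unit masses. Invariant under rigid transforms and
    linear in uniform coordinate scaling.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("radius of gyration of an empty point set")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != coords.shape[0] or np.any(masses <= 0):
        raise ValueError("masses must be positive and match the point count")
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def chain_radius_of_gyration(chain: ChainStructure) -> float:
    """Heavy-atom, element-mass-weighted Rg of a chain."""
    atoms = [a for r in chain.residues for a in r.heavy_atoms()]
    if not atoms:
        raise ValueError(f"{chain.source_id}: no heavy atoms")
    coords = np.array([a.position for a in atoms])
    masses = np.array([ATOMIC_MASS.get(a.element.upper(), 12.011) for a in atoms])
    return radius_of_gyration(coords, masses)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------


@dataclass
class SasaResult:
    residue_labels: list[str]
    absolute: np.ndarray    # per-residue Å²
    relative: np.ndarray    # per-residue fraction of Gly-X-Gly maximum (nan if unknown)

    @property
    def total(self) -> float:
        return float(self.absolute.sum())


def sasa(chain: ChainStructure,
         probe_radius: float = DEFAULT_CONFIG.sasa_probe_radius,
         points_per_atom: int = DEFAULT_CONFIG.sasa_points) -> SasaResult:
    """Shrake–Rupley numeric SASA over heavy atoms.

    Returns absolute per-residue areas (Å²) and relative exposures
    normalized by the Gly-X-Gly theoretical maximum of each residue type.
    Residue types without a tabulated maximum get ``nan`` relative SASA and
    a warning.
    """
    import biotite.structure as struc

    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    atoms = [(i, a) for i, res in enumerate(chain.residues)
             for a in res.heavy_atoms()]
    if not atoms:
        raise ValueError(f"{chain.source_id}: no heavy atoms for SASA")
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a.position for _, a in atoms], dtype=np.float32)
    arr.element = np.array([a.element.upper() for _, a in atoms])
    arr.atom_name = np.array([a.name for _, a in atoms])
    arr.res_id = np.array([chain.residues[i].seq_number for i, _ in atoms])
    arr.res_name = np.array([chain.residues[i].name3 for i, _ in atoms])
    arr.chain_id = np.array([chain.chain_id or "A"] * n)
    per_atom = struc.sasa(arr, probe_radius=probe_radius,
                          point_number=points_per_atom, vdw_radii="Single")
    per_atom = np.nan_to_num(per_atom, nan=0.0)

    absolute = np.zeros(chain.length())
    for (i, _), area in zip(atoms, per_atom):
        absolute[i] += area
    relative = np.full(chain.length(), np.nan)
    unknown = []
    for i, res in enumerate(chain.residues):
        ref = MAX_SASA_GXG.get(res.name3)
        if ref is None:
            unknown.append(res.name3)
        else:
            relative[i] = absolute[i] / ref
    if unknown:
        warnings.warn(
            f"no relative-SASA normalization for residue types {sorted(set(unknown))}; "
            "absolute values only", stacklevel=2)
    labels = [r.label for r in chain.residues]
    return SasaResult(labels, absolute, relative)


# ---------------------------------------------------------------------------
# Torsion helper
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))
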
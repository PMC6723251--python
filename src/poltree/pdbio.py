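"""PDB-format coordinate I/O with the conventions used by the superposition pipeline.

Reads and writes fixed-column PDB v3.3 ``ATOM``/``HETATM``/``TITLE``/``TER``/``END``
records.  Output files deliberately carry *only* the TITLE header: all other header
records of the source entry are stripped, and no CRYST1/symmetry records are emitted
because the symmetry operators of a reoriented crystal structure are no longer valid.

The module also provides the small geometric vocabulary shared by the rest of the
package: :class:`RigidTransform` (proper rotation + translation), Cα trace extraction,
metal-ion extraction, and the output file-naming convention
``<pdbid>_<chain>-<set>.pdb`` (uppercase basenames for representative seed structures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "AtomRecord",
    "StructureModel",
    "CaTrace",
    "RigidTransform",
    "IonRecord",
    "PdbError",
    "PdbParseError",
    "ChainNotFoundError",
    "DEFAULT_METALS",
    "read_structure",
    "write_structure",
    "extract_ca_trace",
    "apply_transform",
    "output_filename",
    "extract_metal_ions",
    "format_atom_line",
]

#: Metal elements recognised when pooling HETATM ions.  Magnesium and calcium are the
#: catalytically relevant species; the remainder are ions routinely modelled in
#: crystallographic practice.  User-overridable wherever it is consumed.
DEFAULT_METALS = frozenset(
    {"MG", "MN", "CA", "ZN", "NA", "K", "SR", "CS", "CD", "CO", "NI", "PB", "LU"}
)

_ORTHO_TOL = 1e-8


class PdbError(ValueError):
    """Base class for coordinate-file errors."""


class PdbParseError(PdbError):
    """Malformed or empty PDB input."""


class ChainNotFoundError(PdbError):
    """Requested chain identifier absent from the model."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion ``x -> R @ x + t``.

    The rotation must be proper orthogonal (``R^T R = I`` and ``det R = +1`` within
    1e-8); reflections are rejected at construction time so that no improper
    transform can propagate through the pipeline.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        if np.max(np.abs(R.T @ R - np.eye(3))) >= _ORTHO_TOL:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) >= _ORTHO_TOL:
            raise ValueError("improper rotation (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis: Sequence[float], angle_deg: float,
                   translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` (through the origin), then translate."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        th = math.radians(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))


@dataclass
class AtomRecord:
    """One fixed-column coordinate line."""

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    record_kind: str = "ATOM"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite atom position")


@dataclass
class StructureModel:
    """A single model's atoms from one PDB entry, in file order."""

    pdb_id: str
    title: str
    atoms: list[AtomRecord]
    model_number: int = 1

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class CaTrace:
    """Ordered Cα coordinates and residue identities for one chain."""

    pdb_id: str
    chain_id: str
    residues: list[tuple[int, str, str]]  # (residue_seq, insertion_code, residue_name)
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.residues) != len(self.coords):
            raise ValueError("residue list and coordinate array length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def source(self) -> tuple[str, str]:
        return (self.pdb_id, self.chain_id)

    @property
    def sequence(self) -> str:
        """One-letter sequence; non-standard residues map to 'X'."""
        return "".join(seq1(name, undef_code="X") for _, _, name in self.residues)


@dataclass(frozen=True)
class IonRecord:
    """A metal ion extracted from a HETATM record, tagged with its source file."""

    element: str
    position: np.ndarray
    source_file: str
    source_chain: str
    residue_seq: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if not self.source_file:
            raise ValueError("ion record requires a source file label")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _infer_element(raw_name: str) -> str:
    """Element from the 4-character atom-name field (PDB justification rules).

    A non-blank, non-digit character in column 13 indicates a two-letter element
    (``CA  `` = calcium); otherwise the element is the first alphabetic character
    (`` CA `` = alpha carbon, ``1HB `` = hydrogen).
    """
    f = raw_name.ljust(4)
    if f[0] != " " and not f[0].isdigit():
        return f[:2].strip().upper()
    for ch in f:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        raw_name = line[12:16]
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(raw_name)
        serial_field = line[6:11].strip()
        return AtomRecord(
            serial=int(serial_field) if serial_field else 0,
            name=raw_name.strip(),
            altloc=line[16].strip(),
            residue_name=line[17:20].strip(),
            chain_id=line[21].strip(),
            residue_seq=int(line[22:26]),
            insertion_code=line[26].strip() if len(line) > 26 else "",
            position=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
            occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
            b_factor=float(line[60:66]) if line[60:66].strip() else 0.0,
            element=element,
            record_kind=line[:6].strip(),
        )
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed coordinate record at line {lineno}: {exc}") from exc


def read_structure(path: str | Path, model_choice: int | None = None) -> StructureModel:
    """Read one model from a PDB file.

    Parameters
    ----------
    path:
        PDB-format file with at least one ATOM/HETATM record.
    model_choice:
        MODEL serial to keep for multi-model files; default is the first model.
        Single-model files ignore this parameter.

    Only TITLE header content is retained (concatenated across continuation
    records); all other header records are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")

    title_parts: list[str] = []
    atoms_by_model: dict[int, list[AtomRecord]] = {}
    current_model: int | None = None
    saw_model_record = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title_parts.append(line[10:80].strip())
            elif rec.startswith("MODEL"):
                saw_model_record = True
                try:
                    current_model = int(line[10:14])
                except ValueError:
                    current_model = len(atoms_by_model) + 1
            elif rec.startswith("ENDMDL"):
                current_model = None
            elif rec.startswith(("ATOM  ", "HETATM")) or rec.rstrip() in ("ATOM", "HETATM"):
                model_no = current_model if current_model is not None else (
                    1 if not saw_model_record else 0
                )
                if saw_model_record and current_model is None:
                    # coordinate record outside MODEL/ENDMDL in a multi-model file
                    model_no = 1
                atoms_by_model.setdefault(model_no, []).append(
                    _parse_atom_line(line.rstrip("\n"), lineno)
                )

    if not atoms_by_model:
        raise PdbParseError(f"no coordinate records in {path}")

    if model_choice is None:
        model_no = next(iter(atoms_by_model))
    else:
        if model_choice not in atoms_by_model:
            raise PdbParseError(f"model {model_choice} not present in {path}")
        model_no = model_choice

    stem = path.stem
    pdb_id = stem.split("_")[0].split("-")[0][:4] or stem
    return StructureModel(
        pdb_id=pdb_id,
        title=" ".join(p for p in title_parts if p),
        atoms=atoms_by_model[model_no],
        model_number=model_no,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _name_field(name: str, element: str) -> str:
    if len(name) >= 4 or len(element) == 2:
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)[:4]


def format_atom_line(atom: AtomRecord, serial: int | None = None) -> str:
    """One fixed-column coordinate line (no trailing newline)."""
    s = atom.serial if serial is None else serial
    x, y, z = atom.position
    return (
        f"{atom.record_kind:<6}{min(s, 99999):>5} {_name_field(atom.name, atom.element)}"
        f"{atom.altloc or ' '}{atom.residue_name:>3} {atom.chain_id or ' '}"
        f"{atom.residue_seq:>4}{atom.insertion_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2}"
    )


def _title_lines(title: str) -> list[str]:
    """TITLE record with standard continuation numbering, wrapped at word breaks."""
    if not title:
        return []
    words = title.split()
    chunks: list[str] = []
    cur = ""
    for w in words:
        cand = f"{cur} {w}".strip()
        if len(cand) <= 69:
            cur = cand
        else:
            if cur:
                chunks.append(cur)
            cur = w
    if cur:
        chunks.append(cur)
    lines = []
    for i, chunk in enumerate(chunks):
        if i == 0:
            lines.append(f"TITLE     {chunk}")
        else:
            lines.append(f"TITLE  {i + 1:>3} {chunk}")
    return lines


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a model in fixed-column PDB format.

    TITLE records come first, coordinates keep file order with sequential serials,
    TER records close each protein chain, and END terminates the file.  No CRYST1
    or symmetry records are written.
    """
    path = Path(path)
    lines = _title_lines(model.title)
    serial = 0
    atoms = model.atoms
    for i, atom in enumerate(atoms):
        serial += 1
        lines.append(format_atom_line(atom, serial))
        if atom.record_kind == "ATOM":
            nxt = atoms[i + 1] if i + 1 < len(atoms) else None
            if nxt is None or nxt.chain_id != atom.chain_id or nxt.record_kind != "ATOM":
                lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_ca_trace(model: StructureModel, chain_id: str) -> CaTrace:
    """Ordered Cα trace for one chain.

    One Cα per (residue number, insertion code), in file order.  HETATM records are
    excluded.  Alternate locations are resolved to the highest-occupancy conformer,
    ties broken by altloc character order, so the trace is a deterministic single
    conformer.
    """
    chain_atoms = [a for a in model.atoms if a.record_kind == "ATOM" and a.chain_id == chain_id]
    if not chain_atoms:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {model.pdb_id}")

    best: dict[tuple[int, str], AtomRecord] = {}
    order: list[tuple[int, str]] = []
    for a in chain_atoms:
        if a.name != "CA":
            continue
        key = (a.residue_seq, a.insertion_code)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (-a.occupancy, a.altloc) < (-b.occupancy, b.altloc):
                best[key] = a
    if not order:
        raise PdbError(f"chain {chain_id!r} has no CA atoms in {model.pdb_id}")

    residues = [(k[0], k[1], best[k].residue_name) for k in order]
    coords = np.array([best[k].position for k in order], dtype=float)
    return CaTrace(model.pdb_id, chain_id, residues, coords)


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Move *every* atom of the entry (all chains, heteroatoms) by ``x -> R x + t``.

    Atom order and identities are unchanged; only positions move, so all
    interatomic distances are preserved.
    """
    pos = np.array([a.position for a in model.atoms], dtype=float)
    new_pos = t.apply(pos)
    new_atoms = [replace(a, position=new_pos[i]) for i, a in enumerate(model.atoms)]
    return StructureModel(model.pdb_id, model.title, new_atoms, model.model_number)


def output_filename(pdb_id: str, chain_id: str, set_name: str,
                    representative: bool = False) -> str:
    """Output naming convention: ``<pdbid>_<Chain>-<set>.pdb``.

    PDB id and set name are lowercased for ordinary entries; the chain identifier
    keeps its case.  Representative seed structures are named by their uppercase
    basename alone (e.g. ``FLAV.pdb``), with no chain or set suffix.
    """
    if not pdb_id:
        raise ValueError("empty pdb_id")
    if representative:
        return f"{pdb_id.upper()}.pdb"
    if not set_name:
        raise ValueError("empty set name")
    return f"{pdb_id.lower()}_{chain_id}-{set_name.lower()}.pdb"


def extract_metal_ions(
    model: StructureModel,
    source_file: str,
    metals: Iterable[str] = DEFAULT_METALS,
) -> list[IonRecord]:
    """All HETATM records whose element belongs to the metal set.

    Waters and organic heteroatoms are excluded by the element filter; protein
    alpha-carbons named ``CA`` are excluded because they are ATOM records with
    element C, not HETATM records with element Ca.
    """
    metal_set = {m.upper() for m in metals}
    out = []
    for a in model.atoms:
        if a.record_kind == "HETATM" and a.element.upper() in metal_set:
            out.append(
                IonRecord(
                    element=a.element.upper(),
                    position=a.position,
                    source_file=source_file,
                    source_chain=a.chain_id,
                    residue_seq=a.residue_seq,
                )
            )
    return out
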
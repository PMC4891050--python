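"""Protein structures, pocket spheres and residue selections.

The screening target is a protein pocket — in the motivating application the
dimerization interface of the CD147 extracellular domain, whose key residues
(e.g. Glu64, Glu73) line a cleft deep enough to accept a small molecule.  This
module parses single-model PDB files into a light-weight residue/atom object
model, defines the active-site sphere that delimits the pocket, and selects
pocket and interface residues by heavy-atom distance.

Conventions
-----------
* Only the first MODEL of a file is read; alternate locations other than
  ``'A'`` or blank are dropped.
* "Heavy atom" means any element other than H or D.
* Residue numbering follows the file verbatim, so "Glu64" always refers to
  the author numbering of the input structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdbio

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "PocketSphere",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "select_pocket",
    "interface_residues",
    "sphere_from_residues",
    "pocket_report",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A single atom from an ATOM/HETATM record."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    serial: int

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue: 3-letter name, author numbering, chain id and atoms."""

    name: str
    number: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)

    @property
    def label(self) -> str:
        """Human-readable label like ``Glu64``."""
        return self.name.capitalize() + str(self.number)


@dataclass
class ProteinStructure:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError(f"no residue {chain}/{number} in structure {self.id!r}")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for r in self.residues for a in r.atoms if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms if a.is_heavy]


@dataclass(frozen=True)
class PocketSphere:
    """The active-site sphere restricting map generation and screening."""

    center: np.ndarray  # shape (3,)
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("pocket sphere radius must be > 0")

    def contains(self, point: np.ndarray, slack: float = 0.0) -> bool:
        return float(np.linalg.norm(np.asarray(point, float) - self.center)) <= self.radius + slack


# ---------------------------------------------------------------------------
# PDB I/O (via biotite; fixed-column dialect)
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[:1].upper()


def parse_pdb(text: str, *, keep_hetero: bool = False, keep_waters: bool = False,
              structure_id: str = "structure") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Reads the first model only; alternate locations keep 'A'/blank.  HETATM
    records and waters are skipped unless requested.  The element symbol is
    taken from columns 77-78, falling back to inference from the atom name.
    """
    lines = text.splitlines()
    atom_lines = [ln for ln in lines if ln.startswith(("ATOM  ", "HETATM"))]
    if not atom_lines:
        raise PDBParseError("no ATOM records found in input")
    # Pre-validate coordinate fields so errors can name the offending line.
    for i, ln in enumerate(lines):
        if ln.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = ln[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"unparseable coordinate field {fieldtxt!r} on line {i + 1}: {ln!r}"
                    ) from None
    try:
        pdb_file = _pdbio.PDBFile.read(io.StringIO(text))
        arr = pdb_file.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:  # pragma: no cover - biotite-internal failure modes
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc

    structure = ProteinStructure(id=structure_id)
    current: Residue | None = None
    for i in range(arr.array_length()):
        if arr.hetero[i]:
            resname = str(arr.res_name[i]).strip()
            if resname in _WATER_NAMES and not keep_waters:
                continue
            if resname not in _WATER_NAMES and not keep_hetero:
                continue
        name = str(arr.atom_name[i]).strip()
        element = str(arr.element[i]).strip().upper()
        if not element:
            element = _element_from_name(name)
        atom = Atom(
            name=name,
            element=element,
            position=np.array(arr.coord[i], dtype=float),
            serial=int(arr.atom_id[i]),
        )
        chain = str(arr.chain_id[i]).strip()
        number = int(arr.res_id[i])
        resname = str(arr.res_name[i]).strip()
        if current is None or current.chain != chain or current.number != number:
            current = Residue(name=resname, number=number, chain=chain)
            structure.residues.append(current)
        current.atoms.append(atom)
    if not structure.residues:
        raise PDBParseError("no residues remained after filtering")
    return structure


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure back to PDB text (same dialect parse_pdb reads)."""
    n_atoms = sum(len(r.atoms) for r in structure.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for r in structure.residues:
        for a in r.atoms:
            arr.chain_id[i] = r.chain
            arr.res_id[i] = r.number
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.coord[i] = a.position
            i += 1
    arr.hetero[:] = False
    pdb_file = _pdbio.PDBFile()
    pdb_file.set_structure(arr)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_pocket(structure: ProteinStructure, sphere: PocketSphere) -> list[Residue]:
    """Residues with >=1 heavy atom inside the sphere (boundary inclusive)."""
    out = []
    for r in structure.residues:
        pts = r.heavy_coords()
        if pts.size and np.any(np.linalg.norm(pts - sphere.center, axis=1) <= sphere.radius):
            out.append(r)
    return out


def interface_residues(a: ProteinStructure, b: ProteinStructure, cutoff: float) -> list[Residue]:
    """Residues of `a` with a heavy atom within `cutoff` of any heavy atom of `b`."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    b_pts = b.heavy_coords()
    if b_pts.size == 0:
        return []
    out = []
    for r in a.residues:
        pts = r.heavy_coords()
        if pts.size == 0:
            continue
        d = np.linalg.norm(pts[:, None, :] - b_pts[None, :, :], axis=2)
        if np.any(d <= cutoff):
            out.append(r)
    return out


def sphere_from_residues(structure: ProteinStructure,
                         selection: list[tuple[str, int]],
                         padding: float) -> PocketSphere:
    """Smallest centroid-centered sphere covering the selected residues' heavy
    atoms, grown by `padding` Angstrom."""
    pts = []
    for chain, number in selection:
        res = structure.residue(chain, number)  # raises KeyError if absent
        pts.append(res.heavy_coords())
    coords = np.vstack(pts)
    center = coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(coords - center, axis=1))) + padding
    return PocketSphere(center=center, radius=max(radius, 1e-9))


def pocket_report(structure: ProteinStructure, sphere: PocketSphere) -> str:
    """TSV report: chain, resSeq, resName, min heavy-atom distance to center."""
    rows = ["chain\tresSeq\tresName\tmin_dist_to_center"]
    for r in select_pocket(structure, sphere):
        d = float(np.min(np.linalg.norm(r.heavy_coords() - sphere.center, axis=1)))
        rows.append(f"{r.chain}\t{r.number}\t{r.name}\t{d:.3f}")
    return "\n".join(rows) + "\n"
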
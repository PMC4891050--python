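"""Deterministic synthetic inputs for every stage of the pipeline.

Real inputs to a campaign like this are a crystal structure, a commercial
compound library and wet-lab readout tables.  None can ship with the package,
so each generator below emits a desk-scale stand-in together with a ground-
truth manifest, and every generator is a pure function of its arguments and
seed (byte-identical reruns):

* :func:`make_toy_pocket` - a 12-residue horseshoe cleft written as PDB text.
  The residue roster echoes the targeted dimer-interface neighborhood (two
  glutamates numbered 64 and 73, a lysine, serine/threonine donors, several
  hydrophobic residues); side chains point into the cleft so the interaction
  map projects features into open space.  Geometry is idealized, not a
  physical fold.
* :func:`make_planted_library` - an SDF of multi-fragment probe molecules.
  Actives carry one conformer whose perceived features sit exactly on a given
  hypothesis (at most one feature displaced by a stated amount); decoys omit
  at least one required feature kind or break the pairwise geometry.  Each
  molecule carries a distinct halogen/chalcogen tag fragment so the actives
  are structurally diverse under path fingerprints.
* :func:`make_screen_table` - an SPR/zymography readout table with exact
  planted counts of RU hits, inhibition hits and their overlap.
* :func:`make_dose_response` - 4PL dose-response data with known parameters
  and seeded Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Geometry import Point3D

from .structure import Atom, PocketSphere, ProteinStructure, Residue, write_pdb
from .imap import DONOR, ACCEPTOR, HYDROPHOBIC, Hypothesis
from .ligands import Ligand, write_sdf
from .triage import four_pl

__all__ = [
    "ToyPocket",
    "make_toy_pocket",
    "make_planted_library",
    "make_screen_table",
    "make_dose_response",
]

POCKET_CENTER = np.zeros(3)
POCKET_RADIUS = 11.0
RING_RADIUS = 10.0  # backbone circle; side-chain tips stay >= ~4 A from center

# (name, intended extra side-chain site kinds beyond backbone donor+acceptor)
_ROSTER = [
    ("LEU", [HYDROPHOBIC]),
    ("LYS", [DONOR]),
    ("GLU", [ACCEPTOR, ACCEPTOR]),
    ("ASP", [ACCEPTOR, ACCEPTOR]),
    ("ALA", [HYDROPHOBIC]),
    ("LEU", [HYDROPHOBIC]),
    ("SER", [DONOR, ACCEPTOR]),
    ("PHE", [HYDROPHOBIC]),
    ("VAL", [HYDROPHOBIC]),
    ("GLY", []),
    ("THR", [DONOR, ACCEPTOR]),
    ("GLU", [ACCEPTOR, ACCEPTOR]),
]
_NUMBERS = [62, 63, 64, 65, 66, 67, 68, 69, 70, 71, 72, 73]


@dataclass
class ToyPocket:
    pdb_text: str
    manifest: dict

    @property
    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=1)


def _sidechain_atoms(name: str, base: np.ndarray, u: np.ndarray,
                     t: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Idealized side chain along the inward unit vector u (tangent t)."""
    if name == "GLY":
        return []
    atoms = [("CB", base + 1.5 * u)]
    if name == "ALA":
        return atoms
    if name == "SER":
        atoms.append(("OG", base + 2.9 * u))
    elif name == "THR":
        atoms += [("OG1", base + 2.9 * u), ("CG2", base + 1.5 * u + 1.4 * t)]
    elif name == "VAL":
        atoms += [("CG1", base + 2.6 * u + 0.9 * t), ("CG2", base + 2.6 * u - 0.9 * t)]
    elif name == "LEU":
        atoms += [("CG", base + 2.9 * u),
                  ("CD1", base + 4.0 * u + 0.9 * t), ("CD2", base + 4.0 * u - 0.9 * t)]
    elif name == "PHE":
        cg = base + 2.9 * u
        atoms.append(("CG", cg))
        ring = [("CD1", 1.4, 0.8), ("CD2", 1.4, -0.8), ("CE1", 2.5, 0.8),
                ("CE2", 2.5, -0.8), ("CZ", 3.0, 0.0)]
        atoms += [(nm, cg + a * u + b * t) for nm, a, b in ring]
    elif name in ("GLU", "ASP"):
        cg = base + 2.9 * u
        atoms.append(("CG", cg))
        if name == "GLU":
            cd = base + 4.2 * u
            atoms += [("CD", cd), ("OE1", cd + 1.0 * u + 0.8 * t),
                      ("OE2", cd + 1.0 * u - 0.8 * t)]
        else:
            atoms += [("OD1", cg + 1.0 * u + 0.8 * t), ("OD2", cg + 1.0 * u - 0.8 * t)]
    elif name == "LYS":
        atoms += [("CG", base + 2.9 * u), ("CD", base + 3.8 * u),
                  ("CE", base + 4.8 * u), ("NZ", base + 5.8 * u)]
    return atoms


def make_toy_pocket(seed: int = 1) -> ToyPocket:
    """A 12-residue concave cleft around the origin, as PDB text + manifest."""
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    manifest_res = []
    serial = 1
    for i, ((name, extra_sites), number) in enumerate(zip(_ROSTER, _NUMBERS)):
        theta = 2.0 * np.pi * i / len(_ROSTER)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        base = RING_RADIUS * radial + (0.8 if i % 2 else -0.8) * z
        u = -radial  # inward
        res = Residue(name=name, number=number, chain="A")
        backbone = [("N", base + 1.45 * t + 0.4 * z), ("CA", base),
                    ("C", base - 1.5 * t), ("O", base - 1.5 * t + 1.23 * u)]
        for atom_name, pos in backbone + _sidechain_atoms(name, base, u, t):
            pos = pos + rng.normal(0.0, 0.05, size=3)
            element = "O" if atom_name.startswith("O") else (
                "N" if atom_name.startswith("N") else "C")
            res.atoms.append(Atom(name=atom_name, element=element,
                                  position=pos, serial=serial))
            serial += 1
        residues.append(res)
        manifest_res.append({
            "chain": "A", "number": number, "name": name,
            "sites": [DONOR, ACCEPTOR] + extra_sites,  # backbone N/O + side chain
        })
    structure = ProteinStructure(id=f"toy-pocket-seed{seed}", residues=residues)
    pdb_text = f"REMARK 999 pharmscreen toy pocket seed={seed}\n" + write_pdb(structure)
    manifest = {
        "seed": seed,
        "n_residues": len(residues),
        "pocket_center": [0.0, 0.0, 0.0],
        "pocket_radius": POCKET_RADIUS,
        "residues": manifest_res,
    }
    return ToyPocket(pdb_text=pdb_text, manifest=manifest)


def toy_pocket_sphere() -> PocketSphere:
    return PocketSphere(center=POCKET_CENTER.copy(), radius=POCKET_RADIUS)


# ---------------------------------------------------------------------------
# Planted ligand libraries
# ---------------------------------------------------------------------------

_TAGS = ["F", "Cl", "Br", "I", "S", "P"]  # one-heteroatom tags for diversity


def _add_fragment(mol: RWMol, coords: list[np.ndarray], atoms: list[tuple[str, np.ndarray]],
                  bonds: list[tuple[int, int, Chem.BondType]]) -> None:
    offset = mol.GetNumAtoms()
    for sym, pos in atoms:
        mol.AddAtom(Chem.Atom(sym))
        coords.append(np.asarray(pos, float))
    for i, j, order in bonds:
        mol.AddBond(offset + i, offset + j, order)


def _feature_fragment(kind: str, position: np.ndarray, inward: np.ndarray
                      ) -> tuple[list[tuple[str, np.ndarray]],
                                 list[tuple[int, int, Chem.BondType]]]:
    """A minimal fragment whose perceived feature of `kind` sits at `position`.

    `inward` points from the feature position toward the cleft interior, where
    auxiliary atoms are safe from protein clashes.
    """
    if kind == DONOR:  # methanol: O (donor, has implicit H) at the feature point
        return ([("O", position), ("C", position + 1.43 * inward)],
                [(0, 1, Chem.BondType.SINGLE)])
    if kind == ACCEPTOR:  # formaldehyde: carbonyl O at the feature point
        return ([("O", position), ("C", position + 1.22 * inward)],
                [(0, 1, Chem.BondType.DOUBLE)])
    # propane: collinear run of three apolar carbons centered on the feature,
    # oriented along z -- the cleft's open axis in the generated pockets
    w = np.array([0.0, 0.0, 1.0])
    return ([("C", position - 1.4 * w), ("C", position), ("C", position + 1.4 * w)],
            [(0, 1, Chem.BondType.SINGLE), (1, 2, Chem.BondType.SINGLE)])


def _assemble(lig_id: str, fragments) -> Ligand:
    mol = RWMol()
    coords: list[np.ndarray] = []
    for atoms, bonds in fragments:
        _add_fragment(mol, coords, atoms, bonds)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, pos in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*[float(x) for x in pos]))
    m.AddConformer(conf, assignId=True)
    return Ligand(id=lig_id, mol=m, multi_fragment=True)


def make_planted_library(hypothesis: Hypothesis, n_active: int = 5, n_decoy: int = 45,
                         displacement: float = 0.5, seed: int = 1
                         ) -> tuple[str, dict[str, str]]:
    """SDF text of actives planted on `hypothesis` plus kind-deficient /
    geometry-breaking decoys, with a truth-label dict.

    Each active covers every hypothesis feature exactly, except one randomly
    chosen feature displaced by exactly `displacement` (must be below the
    smallest feature tolerance).  Decoys either omit every fragment able to
    present some required kind, or present all kinds at pairwise distances
    inflated beyond tolerance compatibility.
    """
    min_tol = min(f.tolerance for f in hypothesis.features)
    if displacement >= min_tol:
        raise ValueError(f"displacement {displacement} must be < min tolerance {min_tol}")
    rng = np.random.default_rng(seed)
    center = hypothesis.positions.mean(axis=0)
    kinds_present = sorted(set(f.kind for f in hypothesis.features))
    # feasible omission sets: dropping a donor fragment never removes an
    # acceptor, but any donor fragment (O-H / N-H) is also an acceptor, so a
    # decoy without acceptors must drop donors too.
    omit_options = [frozenset([DONOR]), frozenset([HYDROPHOBIC]),
                    frozenset([DONOR, ACCEPTOR])]
    omit_options = [o for o in omit_options if o & set(kinds_present)]

    def inward(pos: np.ndarray) -> np.ndarray:
        v = center - pos
        n = np.linalg.norm(v)
        return np.array([1.0, 0.0, 0.0]) if n < 1e-9 else v / n

    ligands: list[Ligand] = []
    labels: dict[str, str] = {}

    for a in range(n_active):
        displaced_idx = int(rng.integers(len(hypothesis.features))) if displacement > 0 else -1
        fragments = []
        for i, feat in enumerate(hypothesis.features):
            pos = feat.position.copy()
            if i == displaced_idx:
                v = rng.normal(size=3)
                pos = pos + displacement * v / np.linalg.norm(v)
            fragments.append(_feature_fragment(feat.kind, pos, inward(pos)))
        tag = _TAGS[a % len(_TAGS)]
        fragments.append(([("C", center), (tag, center + 1.8 * np.array([0.0, 0.0, 1.0]))],
                          [(0, 1, Chem.BondType.SINGLE)]))
        lig_id = f"ACT-{a + 1:03d}"
        ligands.append(_assemble(lig_id, fragments))
        labels[lig_id] = "active"

    for d in range(n_decoy):
        mode = d % 2
        fragments = []
        if mode == 0:  # kind-deficient
            omit = omit_options[d % len(omit_options)]
            label = "decoy_missing_" + "_".join(sorted(omit))
            for feat in hypothesis.features:
                if feat.kind in omit:
                    continue
                pos = feat.position + rng.normal(0.0, 0.3, size=3)
                fragments.append(_feature_fragment(feat.kind, pos, inward(pos)))
            if not fragments:
                fragments.append(_feature_fragment(
                    HYDROPHOBIC if HYDROPHOBIC not in omit else ACCEPTOR,
                    center, np.array([1.0, 0.0, 0.0])))
        else:  # geometry-breaking: all kinds, pairwise distances inflated
            label = "decoy_geometry"
            scale = 3.0 + 0.5 * (d % 4)
            for feat in hypothesis.features:
                pos = center + scale * (feat.position - center)
                fragments.append(_feature_fragment(feat.kind, pos, inward(pos)))
        tag = _TAGS[(d + 3) % len(_TAGS)]
        fragments.append(([("C", center + np.array([0.0, 0.0, -2.0])),
                           (tag, center + np.array([0.0, 1.6, -3.0]))],
                          [(0, 1, Chem.BondType.SINGLE)]))
        lig_id = f"DEC-{d + 1:03d}"
        ligands.append(_assemble(lig_id, fragments))
        labels[lig_id] = label

    return write_sdf(ligands), labels


# ---------------------------------------------------------------------------
# Screen-readout tables
# ---------------------------------------------------------------------------

def make_screen_table(n: int = 100, n_ru_hits: int = 5, n_inh_hits: int = 7,
                      n_overlap: int = 1, ru_min: float = 20.0,
                      inh_min: float = 30.0, seed: int = 1) -> pd.DataFrame:
    """Readout table with exactly the planted hit counts.

    Columns: compound_id, ru, inhibition.  Defaults mirror the reported
    primary-screen structure: 100 compounds, 5 SPR hits (RU > 20), 7
    zymography hits (inhibition > 30 %), 1 compound in both lists.
    """
    if n_overlap > min(n_ru_hits, n_inh_hits):
        raise ValueError("n_overlap cannot exceed either hit count")
    if n_ru_hits + n_inh_hits - n_overlap > n:
        raise ValueError("hit counts exceed table size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    both = order[:n_overlap]
    ru_only = order[n_overlap:n_ru_hits]
    inh_only = order[n_ru_hits:n_ru_hits + n_inh_hits - n_overlap]
    ru = rng.uniform(1.0, max(ru_min - 2.0, 2.0), size=n)
    inh = rng.uniform(-10.0, inh_min - 2.0, size=n)
    ru[both] = rng.uniform(ru_min + 2.0, ru_min + 50.0, size=len(both))
    ru[ru_only] = rng.uniform(ru_min + 2.0, ru_min + 50.0, size=len(ru_only))
    inh[both] = rng.uniform(inh_min + 2.0, 95.0, size=len(both))
    inh[inh_only] = rng.uniform(inh_min + 2.0, 95.0, size=len(inh_only))
    return pd.DataFrame({
        "compound_id": [f"CMP-{i + 1:03d}" for i in range(n)],
        "ru": np.round(ru, 3),
        "inhibition": np.round(inh, 3),
    })


def make_dose_response(bottom: float = 0.0, top: float = 100.0, hill: float = 1.0,
                       ic50: float = 10.0, doses=None, noise_sd: float = 0.0,
                       seed: int = 1) -> pd.DataFrame:
    """4PL curve values at the given doses plus seeded Gaussian noise."""
    if doses is None:
        doses = np.logspace(-1, 2, 8)
    doses = np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    y = four_pl(doses, bottom, top, hill, ic50)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(doses))
    return pd.DataFrame({"dose": doses, "response": y})
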
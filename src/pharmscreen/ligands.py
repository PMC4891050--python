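"""Ligand parsing, physicochemical properties, feature perception, fingerprints.

Small molecules enter the funnel as SMILES (topology only) or SDF V2000
(topology plus 3D conformers).  RDKit supplies the molecular graph, standard
atomic weights, the Wildman-Crippen additive logP and hashed linear-path
fingerprints; aqueous solubility is estimated with the ESOL linear model.
Ligand pharmacophore features (H-bond donor, acceptor, hydrophobic) are
perceived with the same three-kind vocabulary the interaction map uses, so a
ligand can be matched feature-for-feature against a pocket hypothesis:

* donor     - O or N carrying at least one hydrogen,
* acceptor  - any O; N with an available lone pair (not quaternary, not an
  amide N, and aromatic N only when it bears no H),
* hydrophobic - centroid of each all-carbon ring, plus the centroid of every
  connected acyclic run of >=3 apolar carbons (carbons with no N/O neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Ligand",
    "LigandProperties",
    "LigandFeature",
    "Fingerprint",
    "LigandParseError",
    "parse_smiles",
    "parse_smiles_file",
    "parse_sdf",
    "write_sdf",
    "mol_weight",
    "logp_estimate",
    "logs_estimate",
    "n_rotatable",
    "compute_properties",
    "perceive_ligand_features",
    "path_fingerprint",
    "tanimoto",
    "properties_table",
]

# ESOL (Delaney 2004) aqueous-solubility model: log10(S / mol L^-1) as a
# linear function of cLogP, molecular weight, rotatable-bond count and the
# aromatic-atom fraction.  Coefficients as published.
ESOL_INTERCEPT = 0.16
ESOL_COEF_LOGP = -0.63
ESOL_COEF_MW = -0.0062
ESOL_COEF_ROTB = 0.066
ESOL_COEF_AP = -0.74


class LigandParseError(ValueError):
    """Raised when SMILES or SDF input cannot be parsed."""


@dataclass(frozen=True)
class LigandProperties:
    mw: float
    logp: float
    logs: float
    n_rotatable: int


@dataclass(frozen=True)
class LigandFeature:
    kind: str  # donor | acceptor | hydrophobic
    position: np.ndarray
    atom_indices: tuple[int, ...]


@dataclass
class Fingerprint:
    """Hashed linear-path fingerprint (element + bond-order paths)."""

    bits: object  # rdkit ExplicitBitVect
    nbits: int

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


@dataclass
class Ligand:
    """A small molecule: RDKit graph plus optional 3D conformers."""

    id: str
    mol: Chem.Mol
    multi_fragment: bool = False
    properties: LigandProperties | None = None

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def conformer_coords(self, index: int = 0) -> np.ndarray:
        if self.n_conformers == 0:
            raise RuntimeError(f"ligand {self.id!r} has no conformer")
        return np.array(self.mol.GetConformer(index).GetPositions(), dtype=float)

    def heavy_elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    def formula(self) -> str:
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula
        return CalcMolFormula(self.mol)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _guess_offset(text: str) -> int:
    """Best-effort parse-failure offset: first unbalanced bracket, else end."""
    depth = 0
    for i, ch in enumerate(text):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def parse_smiles(text: str, ligand_id: str = "") -> Ligand:
    """Parse one SMILES string; implicit hydrogens resolved to counts."""
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise LigandParseError(
            f"invalid SMILES (error at or before offset {_guess_offset(text)}): {text!r}")
    return Ligand(id=ligand_id or text, mol=mol,
                  multi_fragment=len(Chem.GetMolFrags(mol)) > 1)


def parse_smiles_file(text: str) -> list[Ligand]:
    """One SMILES per line, optional whitespace-separated id."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        lig_id = parts[1].strip() if len(parts) > 1 else smiles
        out.append(parse_smiles(smiles, lig_id))
    return out


def parse_sdf(text: str) -> list[Ligand]:
    """Parse an SDF (V2000) text into ligands with conformers."""
    blocks = [b for b in text.split("$$$$") if b.strip()]
    out = []
    for i, block in enumerate(blocks):
        block = block.lstrip("\n") + "\n"
        mol = Chem.MolFromMolBlock(block, removeHs=False)
        if mol is None:
            raise LigandParseError(f"unparseable SDF block #{i + 1}")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        out.append(Ligand(id=name or f"mol{i + 1}", mol=mol,
                          multi_fragment=len(Chem.GetMolFrags(mol)) > 1))
    return out


def write_sdf(ligands: list[Ligand]) -> str:
    parts = []
    for lig in ligands:
        mol = Chem.Mol(lig.mol)
        mol.SetProp("_Name", lig.id)
        parts.append(Chem.MolToMolBlock(mol, kekulize=True))
        parts.append("$$$$\n")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

def mol_weight(ligand: Ligand) -> float:
    """Average molecular weight (Da), implicit hydrogens included."""
    return float(Descriptors.MolWt(ligand.mol))


def logp_estimate(ligand: Ligand) -> float:
    """Wildman-Crippen atom-additive logP (strictly additive over fragments)."""
    return float(Crippen.MolLogP(ligand.mol))


def n_rotatable(ligand: Ligand) -> int:
    return int(Descriptors.NumRotatableBonds(ligand.mol))


def _aromatic_fraction(mol: Chem.Mol) -> float:
    heavy = mol.GetNumAtoms()
    if heavy == 0:
        return 0.0
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy


def logs_estimate(ligand: Ligand) -> float:
    """ESOL aqueous solubility, log10 mol/L (see module docstring)."""
    return (ESOL_INTERCEPT
            + ESOL_COEF_LOGP * logp_estimate(ligand)
            + ESOL_COEF_MW * mol_weight(ligand)
            + ESOL_COEF_ROTB * n_rotatable(ligand)
            + ESOL_COEF_AP * _aromatic_fraction(ligand.mol))


def compute_properties(ligand: Ligand) -> LigandProperties:
    props = LigandProperties(
        mw=mol_weight(ligand),
        logp=logp_estimate(ligand),
        logs=logs_estimate(ligand),
        n_rotatable=n_rotatable(ligand),
    )
    ligand.properties = props
    return props


def properties_table(ligands: list[Ligand]) -> str:
    """CSV: id, mw, logp, logs, n_rotatable."""
    rows = ["id,mw,logp,logs,n_rotatable"]
    for lig in ligands:
        p = lig.properties or compute_properties(lig)
        rows.append(f"{lig.id},{p.mw:.3f},{p.logp:.3f},{p.logs:.3f},{p.n_rotatable}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Pharmacophore feature perception
# ---------------------------------------------------------------------------

def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for bond in nb.GetBonds():
            other = bond.GetOtherAtom(nb)
            if other.GetIdx() == atom.GetIdx():
                continue
            if other.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def _is_acceptor_nitrogen(atom: Chem.Atom) -> bool:
    if atom.GetFormalCharge() > 0:
        return False
    if atom.GetTotalDegree() >= 4:  # quaternary
        return False
    if _is_amide_nitrogen(atom):
        return False
    if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:  # pyrrole-like
        return False
    return True


def perceive_ligand_features(ligand: Ligand, conformer_index: int = 0) -> list[LigandFeature]:
    """Perceive donor/acceptor/hydrophobic features on one conformer."""
    mol = ligand.mol
    coords = ligand.conformer_coords(conformer_index)
    feats: list[LigandFeature] = []
    for atom in mol.GetAtoms():
        sym, idx = atom.GetSymbol(), atom.GetIdx()
        if sym in ("O", "N") and atom.GetTotalNumHs() >= 1:
            feats.append(LigandFeature("donor", coords[idx].copy(), (idx,)))
        if sym == "O":
            feats.append(LigandFeature("acceptor", coords[idx].copy(), (idx,)))
        elif sym == "N" and _is_acceptor_nitrogen(atom):
            feats.append(LigandFeature("acceptor", coords[idx].copy(), (idx,)))
    # carbocyclic ring centroids
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetSymbol() == "C" for i in ring):
            centroid = coords[list(ring)].mean(axis=0)
            feats.append(LigandFeature("hydrophobic", centroid, tuple(sorted(ring))))
    # acyclic apolar-carbon runs (connected components of >=3 such carbons)
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.IsInRing():
            continue
        if any(nb.GetSymbol() in ("N", "O") for nb in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    seen: set[int] = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in apolar and j not in seen:
                    stack.append(j)
        if len(comp) >= 3:
            centroid = coords[sorted(comp)].mean(axis=0)
            feats.append(LigandFeature("hydrophobic", centroid, tuple(sorted(comp))))
    return feats


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------

def path_fingerprint(ligand: Ligand, max_len: int = 6, nbits: int = 1024) -> Fingerprint:
    """Hashed linear-path fingerprint over paths of length 1..max_len bonds."""
    bv = Chem.RDKFingerprint(ligand.mol, minPath=1, maxPath=max_len, fpSize=nbits,
                             nBitsPerHash=2, branchedPaths=False)
    return Fingerprint(bits=bv, nbits=nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b|; 1.0 when both are empty."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint size mismatch: {a.nbits} vs {b.nbits}")
    sa, sb = a.on_bits, b.on_bits
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union
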
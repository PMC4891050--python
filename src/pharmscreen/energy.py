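"""Pose energy model: nonbonded interaction energy, per-residue decomposition,
rigid-body minimization and hydrogen-bond detection.

The protein-ligand interaction energy is a transparent pairwise nonbonded sum
over heavy-atom pairs within a cutoff,

    E = sum_ij  4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ]
              + 332.0636 q_i q_j / (4 r^2)

with Lorentz-Berthelot combining (arithmetic-mean sigma, geometric-mean eps)
and the distance-dependent dielectric eps(r) = 4r standard for implicit-
solvent pocket scoring.  Partial charges follow a simple documented
heavy-atom scheme (formal charges plus fixed polar-group increments, tables
below); hydrogens are implicit, their charge folded into the bonded heavy
atom.  This is an open analog of docking free-energy rescoring functions and
makes no claim of numeric equivalence with any proprietary score.

Per-residue decomposition attributes each pair term to the protein residue
owning the protein atom; the decomposition over the 10-A residue shell sums
exactly to the shell total, which is what makes the attribution auditable.

"In situ ligand minimization" is realized as deterministic rigid-body (3
translations + 3 rotations) coordinate descent with a shrinking step
schedule; the energy never increases along the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import ProteinStructure, Residue
from .ligands import Ligand

__all__ = [
    "EnergyParams",
    "AtomSet",
    "PoseScore",
    "HBond",
    "SingularityError",
    "ligand_atom_set",
    "protein_atom_set",
    "interaction_energy",
    "per_residue_decomposition",
    "minimize_pose",
    "detect_hbonds",
    "hbond_geometry_ok",
    "per_residue_table",
    "hbond_table",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)

# Per-element Lennard-Jones parameters: sigma (A), epsilon (kcal/mol).
# Generic all-purpose values in the range used by classical force fields.
DEFAULT_LJ: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
    "P": (3.74, 0.200),
    "F": (3.12, 0.061),
    "CL": (3.47, 0.265),
    "BR": (3.60, 0.320),
    "I": (3.83, 0.400),
    "H": (2.47, 0.016),
}
_LJ_FALLBACK = (3.40, 0.100)

# Heavy-atom effective partial charges (e).  Hydrogens are implicit, so a
# donor heavy atom carries its hydrogen's positive charge: the donor face
# must attract acceptors for H-bonds to be favorable in a heavy-atom model.
LIGAND_CHARGE_HYDROXYL_O = +0.20   # O bearing >=1 H (O-H dipole, H side)
LIGAND_CHARGE_ACCEPTOR_O = -0.40   # O without H (carbonyl, ether, ...)
LIGAND_CHARGE_DONOR_N = +0.25      # N bearing >=1 H
LIGAND_CHARGE_ACCEPTOR_N = -0.30   # N without H
# Protein side, by (residue, atom name); element defaults below otherwise.
PROTEIN_SPECIAL_CHARGES: dict[tuple[str, str], float] = {
    ("GLU", "OE1"): -0.57, ("GLU", "OE2"): -0.57, ("GLU", "CD"): +0.34,
    ("ASP", "OD1"): -0.57, ("ASP", "OD2"): -0.57, ("ASP", "CG"): +0.34,
    ("LYS", "NZ"): +0.60,
    ("ARG", "NE"): +0.30, ("ARG", "NH1"): +0.35, ("ARG", "NH2"): +0.35,
    ("SER", "OG"): -0.20, ("THR", "OG1"): -0.20, ("TYR", "OH"): -0.20,
    ("HIS", "ND1"): -0.15, ("HIS", "NE2"): -0.15,
}
PROTEIN_ELEMENT_CHARGES: dict[str, float] = {"O": -0.40, "N": +0.25}
PROTEIN_BACKBONE_CHARGES: dict[str, float] = {"O": -0.40, "N": +0.25, "C": +0.20}


class SingularityError(ValueError):
    """A pair distance collapsed below the numerical floor."""


@dataclass
class EnergyParams:
    lj: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LJ))
    coulomb_constant: float = COULOMB_CONSTANT
    pair_cutoff: float = 10.0  # A
    r_floor: float = 1e-3

    def sigma_eps(self, element: str) -> tuple[float, float]:
        return self.lj.get(element.upper(), _LJ_FALLBACK)


@dataclass
class AtomSet:
    """Parallel arrays describing one side of the interaction."""

    coords: np.ndarray               # (n, 3)
    elements: list[str]
    charges: np.ndarray              # (n,)
    residue_keys: list[tuple[str, int]] | None = None  # protein side only
    labels: list[str] | None = None  # atom names / ids

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        return AtomSet(np.asarray(coords, float), self.elements, self.charges,
                       self.residue_keys, self.labels)


@dataclass
class HBond:
    donor: tuple[str, str]     # (side, atom label), side in {"ligand", "protein"}
    acceptor: tuple[str, str]
    distance: float
    angle: float | None = None  # D-H...A angle, degrees, when explicit H known


@dataclass
class PoseScore:
    total: float
    per_residue: dict[tuple[str, int], float]
    shell: float
    hbonds: list[HBond] = field(default_factory=list)
    residue_labels: dict[tuple[str, int], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Charge assignment
# ---------------------------------------------------------------------------

def ligand_atom_set(ligand: Ligand, coords: np.ndarray | None = None) -> AtomSet:
    """Heavy-atom coordinates, elements and effective charges for a ligand."""
    mol = ligand.mol
    if coords is None:
        coords = ligand.conformer_coords(0)
    coords = np.asarray(coords, float)
    keep, elements, charges, labels = [], [], [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("H", "D"):
            continue
        q = float(atom.GetFormalCharge())
        if sym == "O":
            q += LIGAND_CHARGE_HYDROXYL_O if atom.GetTotalNumHs() >= 1 else LIGAND_CHARGE_ACCEPTOR_O
        elif sym == "N":
            q += LIGAND_CHARGE_DONOR_N if atom.GetTotalNumHs() >= 1 else LIGAND_CHARGE_ACCEPTOR_N
        keep.append(atom.GetIdx())
        elements.append(sym)
        charges.append(q)
        labels.append(f"{sym}{atom.GetIdx()}")
    return AtomSet(coords[keep], elements, np.array(charges, float), None, labels)


def _protein_atom_charge(res: Residue, atom_name: str, element: str) -> float:
    if (res.name, atom_name) in PROTEIN_SPECIAL_CHARGES:
        return PROTEIN_SPECIAL_CHARGES[(res.name, atom_name)]
    if atom_name in ("N", "O", "C", "CA", "OXT"):
        return PROTEIN_BACKBONE_CHARGES.get(atom_name, 0.0)
    return PROTEIN_ELEMENT_CHARGES.get(element.upper(), 0.0)


def protein_atom_set(residues: list[Residue] | ProteinStructure) -> AtomSet:
    """Heavy-atom arrays for a residue list (or whole structure)."""
    if isinstance(residues, ProteinStructure):
        residues = residues.residues
    coords, elements, charges, keys, labels = [], [], [], [], []
    for res in residues:
        for atom in res.atoms:
            if not atom.is_heavy:
                continue
            coords.append(atom.position)
            elements.append(atom.element)
            charges.append(_protein_atom_charge(res, atom.name, atom.element))
            keys.append(res.key)
            labels.append(f"{res.label}:{atom.name}")
    return AtomSet(np.array(coords, float).reshape(-1, 3), elements,
                   np.array(charges, float), keys, labels)


# ---------------------------------------------------------------------------
# Pairwise energy
# ---------------------------------------------------------------------------

def _pair_energy_matrix(lig: AtomSet, prot: AtomSet, params: EnergyParams) -> np.ndarray:
    """(n_lig, n_prot) matrix of pair energies; zero beyond the cutoff."""
    if lig.coords.size == 0 or prot.coords.size == 0:
        return np.zeros((len(lig.elements), len(prot.elements)))
    diff = lig.coords[:, None, :] - prot.coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < params.r_floor):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise SingularityError(
            f"pair distance {r[i, j]:.2e} A below floor (ligand atom {i}, protein atom {j})")
    sig = np.array([params.sigma_eps(e)[0] for e in lig.elements])[:, None] / 2.0 \
        + np.array([params.sigma_eps(e)[0] for e in prot.elements])[None, :] / 2.0
    eps = np.sqrt(np.array([params.sigma_eps(e)[1] for e in lig.elements])[:, None]
                  * np.array([params.sigma_eps(e)[1] for e in prot.elements])[None, :])
    with np.errstate(divide="ignore"):
        sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 ** 2 - sr6)
    coul = params.coulomb_constant * np.outer(lig.charges, prot.charges) / (4.0 * r * r)
    e = lj + coul
    e[r > params.pair_cutoff] = 0.0
    return e


def interaction_energy(lig: AtomSet, prot: AtomSet,
                       params: EnergyParams | None = None) -> float:
    """Total nonbonded ligand-protein interaction energy, kcal/mol."""
    params = params or EnergyParams()
    return float(_pair_energy_matrix(lig, prot, params).sum())


def per_residue_decomposition(lig: AtomSet, structure: ProteinStructure,
                              params: EnergyParams | None = None,
                              shell: float = 10.0) -> PoseScore:
    """Decompose the shell interaction energy residue by residue.

    The shell holds every residue with >=1 heavy atom within `shell` A of any
    ligand heavy atom; the per-residue entries sum exactly to the total, which
    is defined over the shell.
    """
    params = params or EnergyParams()
    shell_residues = []
    for res in structure.residues:
        pts = res.heavy_coords()
        if pts.size == 0 or lig.coords.size == 0:
            continue
        d = np.linalg.norm(pts[:, None, :] - lig.coords[None, :, :], axis=2)
        if np.any(d <= shell):
            shell_residues.append(res)
    prot = protein_atom_set(shell_residues)
    per_residue: dict[tuple[str, int], float] = {r.key: 0.0 for r in shell_residues}
    labels = {r.key: r.label for r in shell_residues}
    if prot.coords.size:
        e = _pair_energy_matrix(lig, prot, params)
        col = e.sum(axis=0)
        for j, key in enumerate(prot.residue_keys):
            per_residue[key] += float(col[j])
    total = float(sum(per_residue.values()))
    return PoseScore(total=total, per_residue=per_residue, shell=shell,
                     residue_labels=labels)


# ---------------------------------------------------------------------------
# Rigid-body minimization
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: int, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s if axis != 1 else s
    R[j, i] = s if axis != 1 else -s
    return R


DEFAULT_STEP_SCHEDULE = (0.4, 0.2, 0.1, 0.05, 0.02, 0.01)


def minimize_pose(lig: AtomSet, prot: AtomSet, params: EnergyParams | None = None,
                  max_iter: int = 50,
                  step_schedule: tuple[float, ...] = DEFAULT_STEP_SCHEDULE,
                  seed: int = 0) -> tuple[AtomSet, list[float]]:
    """Rigid-body coordinate descent on the pose; energy never increases.

    Six degrees of freedom (translation along x/y/z, rotation about x/y/z
    through the ligand centroid) are swept in fixed order; each translation
    step `s` pairs with a rotation step of s/2 radians.  The schedule shrinks
    until `step_schedule` is exhausted; each step size runs at most `max_iter`
    improvement passes.  Deterministic for a given seed (the seed is part of
    the config contract; the default search is seed-independent).

    Returns the minimized AtomSet and the energy trace (starting energy first).
    """
    params = params or EnergyParams()
    coords = lig.coords.copy()
    e0 = interaction_energy(lig.with_coords(coords), prot, params)
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy; run exclusion_check first")
    trace = [e0]
    current = e0

    def moved(c: np.ndarray, dof: int, delta: float) -> np.ndarray:
        if dof < 3:
            out = c.copy()
            out[:, dof] += delta
            return out
        centroid = c.mean(axis=0)
        R = _rotation_matrix(dof - 3, delta)
        return (c - centroid) @ R.T + centroid

    for step in step_schedule:
        for _ in range(max_iter):
            improved = False
            for dof in range(6):
                delta = step if dof < 3 else step / 2.0
                for sign in (+1.0, -1.0):
                    cand = moved(coords, dof, sign * delta)
                    try:
                        e = interaction_energy(lig.with_coords(cand), prot, params)
                    except SingularityError:
                        continue
                    if e < current - 1e-12:
                        coords, current = cand, e
                        trace.append(e)
                        improved = True
            if not improved:
                break
    return lig.with_coords(coords), trace


# ---------------------------------------------------------------------------
# Hydrogen-bond detection
# ---------------------------------------------------------------------------

def hbond_geometry_ok(donor: np.ndarray, acceptor: np.ndarray,
                      hydrogen: np.ndarray | None = None,
                      dmax: float = 3.5, amin: float = 120.0) -> bool:
    """Heavy-atom distance <= dmax and, if an explicit H is given, the
    D-H...A angle >= amin degrees."""
    d = float(np.linalg.norm(np.asarray(donor, float) - np.asarray(acceptor, float)))
    if d > dmax:
        return False
    if hydrogen is not None:
        v1 = np.asarray(donor, float) - np.asarray(hydrogen, float)
        v2 = np.asarray(acceptor, float) - np.asarray(hydrogen, float)
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-9:
            return False
        angle = math.degrees(math.acos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
        if angle < amin:
            return False
    return True


def _dha_angle(donor, hydrogen, acceptor) -> float:
    v1 = np.asarray(donor, float) - np.asarray(hydrogen, float)
    v2 = np.asarray(acceptor, float) - np.asarray(hydrogen, float)
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    return math.degrees(math.acos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))


def detect_hbonds(ligand: Ligand, pose: np.ndarray, structure: ProteinStructure,
                  dmax: float = 3.5, amin: float = 120.0) -> list[HBond]:
    """Geometric H-bonds between a posed ligand and the protein, both
    directions (ligand donor -> protein acceptor and converse).

    Explicit hydrogens, where present (ligand H atoms with pose coordinates,
    protein amide H), impose the D-H...A angle criterion; otherwise bonds are
    accepted on heavy-atom distance alone and the angle is reported absent.
    """
    from .imap import perceive_sites, DONOR, ACCEPTOR

    pose = np.asarray(pose, float)
    mol = ligand.mol
    lig_donors: list[tuple[int, list[int]]] = []   # heavy idx, explicit-H idxs
    lig_acceptors: list[int] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("O", "N"):
            hs = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"]
            if atom.GetTotalNumHs() >= 1 or hs:
                lig_donors.append((atom.GetIdx(), hs))
            if sym == "O" or atom.GetTotalNumHs() == 0:
                lig_acceptors.append(atom.GetIdx())

    sites = perceive_sites(structure.residues)
    prot_donors = [s for s in sites if s.kind == DONOR and s.atom_name != "sidechain"]
    prot_acceptors = [s for s in sites if s.kind == ACCEPTOR]

    def res_label(key: tuple[str, int]) -> str:
        return structure.residue(*key).label

    bonds: list[HBond] = []
    # ligand donor -> protein acceptor
    for idx, hs in lig_donors:
        dpos = pose[idx]
        for site in prot_acceptors:
            dist = float(np.linalg.norm(dpos - site.position))
            if dist > dmax:
                continue
            angle = None
            if hs:
                angle = max(_dha_angle(dpos, pose[h], site.position) for h in hs)
                if angle < amin:
                    continue
            bonds.append(HBond(
                donor=("ligand", f"{mol.GetAtomWithIdx(idx).GetSymbol()}{idx}"),
                acceptor=("protein", f"{res_label(site.residue_key)}:{site.atom_name}"),
                distance=dist, angle=angle))
    # protein donor -> ligand acceptor
    for site in prot_donors:
        res = structure.residue(*site.residue_key)
        h = res.atom("H") if site.atom_name == "N" else None
        for idx in lig_acceptors:
            apos = pose[idx]
            dist = float(np.linalg.norm(site.position - apos))
            if dist > dmax:
                continue
            angle = None
            if h is not None:
                angle = _dha_angle(site.position, h.position, apos)
                if angle < amin:
                    continue
            bonds.append(HBond(
                donor=("protein", f"{res.label}:{site.atom_name}"),
                acceptor=("ligand", f"{mol.GetAtomWithIdx(idx).GetSymbol()}{idx}"),
                distance=dist, angle=angle))
    bonds.sort(key=lambda b: b.distance)
    return bonds


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def per_residue_table(score: PoseScore) -> str:
    """TSV: residue label, energy (kcal/mol), sorted ascending (most favorable first)."""
    rows = ["residue\tenergy_kcal_mol"]
    for key, e in sorted(score.per_residue.items(), key=lambda kv: kv[1]):
        rows.append(f"{score.residue_labels.get(key, str(key))}\t{e:.4f}")
    return "\n".join(rows) + "\n"


def hbond_table(bonds: list[HBond]) -> str:
    rows = ["donor\tacceptor\tdistance_A\tangle_deg"]
    for b in bonds:
        ang = "" if b.angle is None else f"{b.angle:.1f}"
        rows.append(f"{b.donor[0]}:{b.donor[1]}\t{b.acceptor[0]}:{b.acceptor[1]}\t"
                    f"{b.distance:.2f}\t{ang}")
    return "\n".join(rows) + "\n"
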
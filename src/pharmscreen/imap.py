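"""Ludi-style interaction maps, feature clustering and hypothesis enumeration.

From the residues lining a pocket this module derives *protein* interaction
sites (H-bond donors, H-bond acceptors, hydrophobic patches) with a fixed,
deterministic rule table, projects each into the pocket as the *complementary*
ligand-side pharmacophore feature (a protein donor asks for a ligand acceptor
2.9 A along the donor direction, and so on), surrounds the map with exclusion
volumes on every protein heavy atom, condenses near-duplicate features by
complete-linkage clustering, and enumerates 3-7-feature subsets as query
pharmacophore hypotheses.

The feature-placement distances and tolerances below follow canonical
H-bond/hydrophobic-contact geometry and are overridable per call:

===============  =======  ==================================================
parameter        default  meaning
===============  =======  ==================================================
``d_hb``         2.9 A    heavy-atom donor...acceptor projection distance
``d_hp``         4.0 A    hydrophobic-contact projection distance
``clash_dist``   1.5 A    projected features closer than this to any protein
                          heavy atom are discarded
``tolerance``    1.5 A    pharmacophore sphere radius per feature
``r_excl``       1.4 A    exclusion-sphere radius per protein heavy atom
``cutoff``       1.5 A    complete-linkage clustering cutoff
``min_pair_dist``  2.0 A  minimum inter-feature distance within a hypothesis
===============  =======  ==================================================
"""

from __future__ import annotations

import json
import logging
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist

from .structure import PocketSphere, ProteinStructure, Residue

logger = logging.getLogger("pharmscreen.imap")

__all__ = [
    "ProteinSite",
    "PharmacophoreFeature",
    "ExclusionVolume",
    "InteractionMap",
    "Hypothesis",
    "perceive_sites",
    "complement_features",
    "exclusion_volumes",
    "cluster_features",
    "enumerate_hypotheses",
    "build_interaction_map",
    "map_to_json",
    "map_from_json",
]

DONOR = "donor"
ACCEPTOR = "acceptor"
HYDROPHOBIC = "hydrophobic"
KINDS = (DONOR, ACCEPTOR, HYDROPHOBIC)

D_HB = 2.9
D_HP = 4.0
CLASH_DIST = 1.5
TOLERANCE = 1.5
R_EXCL = 1.4
CLUSTER_CUTOFF = 1.5
MIN_PAIR_DIST = 2.0


@dataclass(frozen=True)
class ProteinSite:
    """An interaction-capable point on the protein."""

    kind: str
    position: np.ndarray
    direction: np.ndarray | None  # unit vector or None
    residue_key: tuple[str, int]
    atom_name: str


@dataclass
class PharmacophoreFeature:
    """A ligand-side feature the pocket asks for."""

    kind: str
    position: np.ndarray
    direction: np.ndarray | None = None
    tolerance: float = TOLERANCE
    weight: float = 1.0
    provenance: list[tuple[str, int]] = field(default_factory=list)


@dataclass(frozen=True)
class ExclusionVolume:
    center: np.ndarray
    radius: float
    source_atom: tuple[tuple[str, int], str]


@dataclass
class InteractionMap:
    features: list[PharmacophoreFeature]
    exclusions: list[ExclusionVolume]
    pocket: PocketSphere


@dataclass
class Hypothesis:
    """A 3-7-feature subset of the map used as one query pharmacophore."""

    id: str
    features: list[PharmacophoreFeature]

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features], dtype=float)

    @property
    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]


# ---------------------------------------------------------------------------
# Protein site perception rule table
# ---------------------------------------------------------------------------
# Side-chain H-bond chemistry; direction = atom minus the mean of the listed
# anchor atoms, normalized.  Backbone N/O handled separately.
_SIDECHAIN_SITES: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {
    "SER": [(DONOR, "OG", ("CB",)), (ACCEPTOR, "OG", ("CB",))],
    "THR": [(DONOR, "OG1", ("CB",)), (ACCEPTOR, "OG1", ("CB",))],
    "TYR": [(DONOR, "OH", ("CZ",)), (ACCEPTOR, "OH", ("CZ",))],
    "LYS": [(DONOR, "NZ", ("CE",))],
    "ARG": [(DONOR, "NE", ("CZ",)), (DONOR, "NH1", ("CZ",)), (DONOR, "NH2", ("CZ",))],
    "ASP": [(ACCEPTOR, "OD1", ("CG",)), (ACCEPTOR, "OD2", ("CG",))],
    "GLU": [(ACCEPTOR, "OE1", ("CD",)), (ACCEPTOR, "OE2", ("CD",))],
    "ASN": [(DONOR, "ND2", ("CG",)), (ACCEPTOR, "OD1", ("CG",))],
    "GLN": [(DONOR, "NE2", ("CD",)), (ACCEPTOR, "OE1", ("CD",))],
    "HIS": [
        (DONOR, "ND1", ("CG", "CE1")), (ACCEPTOR, "ND1", ("CG", "CE1")),
        (DONOR, "NE2", ("CD2", "CE1")), (ACCEPTOR, "NE2", ("CD2", "CE1")),
    ],
    "TRP": [(DONOR, "NE1", ("CD1", "CE2"))],
}

_HYDROPHOBIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        return None
    return v / n


def perceive_sites(residues: list[Residue]) -> list[ProteinSite]:
    """Apply the fixed donor/acceptor/hydrophobic rule table to each residue.

    Backbone: amide N is a donor (direction toward the amide H when present,
    else toward the pseudo-H at 2*CA - C); carbonyl O is an acceptor along
    C->O.  Unknown residue names contribute backbone sites only.
    """
    sites: list[ProteinSite] = []
    for res in residues:
        # backbone donor
        n = res.atom("N")
        if n is not None:
            h = res.atom("H")
            if h is not None:
                direction = _unit(h.position - n.position)
            else:
                ca, c = res.atom("CA"), res.atom("C")
                direction = (
                    _unit((2.0 * ca.position - c.position) - n.position)
                    if ca is not None and c is not None else None
                )
            sites.append(ProteinSite(DONOR, n.position.copy(), direction, res.key, "N"))
        # backbone acceptor
        o, c = res.atom("O"), res.atom("C")
        if o is not None:
            direction = _unit(o.position - c.position) if c is not None else None
            sites.append(ProteinSite(ACCEPTOR, o.position.copy(), direction, res.key, "O"))
        # side-chain donors/acceptors
        for kind, atom_name, anchors in _SIDECHAIN_SITES.get(res.name, []):
            a = res.atom(atom_name)
            if a is None:
                continue
            anchor_pts = [res.atom(x).position for x in anchors if res.atom(x) is not None]
            direction = _unit(a.position - np.mean(anchor_pts, axis=0)) if anchor_pts else None
            sites.append(ProteinSite(kind, a.position.copy(), direction, res.key, atom_name))
        # hydrophobic centroid of apolar side-chain carbons
        hp_names = _HYDROPHOBIC_ATOMS.get(res.name)
        if hp_names:
            pts = [res.atom(x).position for x in hp_names if res.atom(x) is not None]
            if pts:
                centroid = np.mean(pts, axis=0)
                sites.append(ProteinSite(HYDROPHOBIC, centroid, None, res.key, "sidechain"))
    return sites


_COMPLEMENT = {DONOR: ACCEPTOR, ACCEPTOR: DONOR, HYDROPHOBIC: HYDROPHOBIC}


def complement_features(sites: list[ProteinSite], structure: ProteinStructure,
                        pocket: PocketSphere, *, d_hb: float = D_HB, d_hp: float = D_HP,
                        clash_dist: float = CLASH_DIST,
                        tolerance: float = TOLERANCE) -> list[PharmacophoreFeature]:
    """Project each protein site into the pocket as its complementary feature.

    Donor/acceptor sites project ``d_hb`` along the site direction (falling
    back to the site->pocket-center direction when no direction could be
    derived); hydrophobic sites project ``d_hp`` toward the pocket center.
    Features outside the pocket sphere or within ``clash_dist`` of a protein
    heavy atom are discarded.
    """
    protein_pts = structure.heavy_coords()
    out: list[PharmacophoreFeature] = []
    for site in sites:
        if site.kind == HYDROPHOBIC:
            direction, dist = _unit(pocket.center - site.position), d_hp
        else:
            direction = site.direction
            if direction is None:
                direction = _unit(pocket.center - site.position)
            dist = d_hb
        if direction is None:
            continue
        pos = site.position + dist * direction
        if not pocket.contains(pos):
            continue
        if protein_pts.size and float(np.min(np.linalg.norm(protein_pts - pos, axis=1))) < clash_dist:
            continue
        out.append(PharmacophoreFeature(
            kind=_COMPLEMENT[site.kind],
            position=pos,
            direction=-direction if site.kind != HYDROPHOBIC else None,
            tolerance=tolerance,
            weight=1.0,
            provenance=[site.residue_key],
        ))
    return out


def exclusion_volumes(structure: ProteinStructure, pocket: PocketSphere,
                      margin: float = 2.0, *, r_excl: float = R_EXCL) -> list[ExclusionVolume]:
    """One forbidden sphere per protein heavy atom near the pocket."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    out = []
    for res, atom in structure.heavy_atoms():
        if np.linalg.norm(atom.position - pocket.center) <= pocket.radius + margin:
            out.append(ExclusionVolume(atom.position.copy(), r_excl, (res.key, atom.name)))
    return out


def _merge_group(group: list[PharmacophoreFeature]) -> PharmacophoreFeature:
    """Weight-averaged representative of a cluster.

    Weighting by accumulated member weight keeps the representative at the
    arithmetic mean of all *original* features it stands for, however many
    condensation passes produced it.
    """
    w = np.array([g.weight for g in group], dtype=float)
    pos = np.average([g.position for g in group], axis=0, weights=w)
    dirs = [(g.direction, g.weight) for g in group if g.direction is not None]
    direction = None
    if dirs:
        direction = _unit(np.average([d for d, _ in dirs], axis=0,
                                     weights=[wt for _, wt in dirs]))
    prov: list[tuple[str, int]] = []
    for g in group:
        for p in g.provenance:
            if p not in prov:
                prov.append(p)
    return PharmacophoreFeature(
        kind=group[0].kind,
        position=pos,
        direction=direction,
        tolerance=float(np.average([g.tolerance for g in group], weights=w)),
        weight=float(w.sum()),
        provenance=prov,
    )


def _cluster_pass(members: list[PharmacophoreFeature],
                  cutoff: float) -> list[PharmacophoreFeature]:
    if len(members) <= 1:
        return list(members)
    pts = np.array([f.position for f in members], dtype=float)
    labels = fcluster(linkage(pdist(pts), method="complete"), t=cutoff,
                      criterion="distance")
    out = []
    for lab in sorted(set(labels), key=lambda L: int(np.argmax(labels == L))):
        group = [members[i] for i in range(len(members)) if labels[i] == lab]
        out.append(group[0] if len(group) == 1 else _merge_group(group))
    return out


def cluster_features(features: list[PharmacophoreFeature],
                     cutoff: float = CLUSTER_CUTOFF) -> list[PharmacophoreFeature]:
    """Condense features by complete-linkage clustering, per kind.

    Each cluster is replaced by a single feature at the mean position of its
    original members, with direction = renormalized mean of member directions
    (absent if no member has one or the mean degenerates), weight = sum of
    member weights, and provenance = union.  Kinds never merge.

    Condensation passes repeat until a fixed point: averaging can leave two
    representatives within the cutoff of each other, so a single linkage cut
    would not be idempotent; iterating to convergence makes re-clustering the
    output at the same cutoff a no-op.  Each pass strictly reduces the count,
    so the loop terminates.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    out: list[PharmacophoreFeature] = []
    for kind in KINDS:
        members = [f for f in features if f.kind == kind]
        while True:
            condensed = _cluster_pass(members, cutoff)
            if len(condensed) == len(members):
                members = condensed
                break
            members = condensed
        out.extend(members)
    return out


def enumerate_hypotheses(features: list[PharmacophoreFeature], kmin: int = 3,
                         kmax: int = 7,
                         min_pair_dist: float = MIN_PAIR_DIST) -> list[Hypothesis]:
    """All kmin..kmax-feature subsets with every pairwise distance >= min_pair_dist.

    Hypothesis ids are the sorted member indices joined by '-'; output order is
    by subset size then lexicographic index order.  ``kmin`` below 3 and
    ``kmax`` above the feature count are clamped with a logged warning.
    """
    n = len(features)
    if kmin < 3:
        logger.warning("kmin=%d below 3; clamped to 3", kmin)
        kmin = 3
    if kmax > n:
        logger.warning("kmax=%d above feature count %d; clamped", kmax, n)
        kmax = n
    if kmax < kmin:
        return []
    pos = np.array([f.position for f in features], dtype=float)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2) if n else np.zeros((0, 0))
    out: list[Hypothesis] = []
    for k in range(kmin, kmax + 1):
        for combo in itertools.combinations(range(n), k):
            ok = all(dist[i, j] >= min_pair_dist
                     for i, j in itertools.combinations(combo, 2))
            if ok:
                out.append(Hypothesis(
                    id="-".join(str(i) for i in combo),
                    features=[features[i] for i in combo],
                ))
    return out


def build_interaction_map(structure: ProteinStructure, pocket: PocketSphere, *,
                          cluster_cutoff: float = CLUSTER_CUTOFF,
                          margin: float = 2.0, **placement) -> InteractionMap:
    """Pocket residues -> sites -> complementary features -> clustered map."""
    from .structure import select_pocket

    residues = select_pocket(structure, pocket)
    sites = perceive_sites(residues)
    feats = complement_features(sites, structure, pocket, **placement)
    feats = cluster_features(feats, cutoff=cluster_cutoff)
    excl = exclusion_volumes(structure, pocket, margin=margin)
    return InteractionMap(features=feats, exclusions=excl, pocket=pocket)


# ---------------------------------------------------------------------------
# Serialization (JSON; exact float round-trip)
# ---------------------------------------------------------------------------

def _feature_to_dict(f: PharmacophoreFeature) -> dict:
    return {
        "kind": f.kind,
        "position": [float(x) for x in f.position],
        "direction": None if f.direction is None else [float(x) for x in f.direction],
        "tolerance": float(f.tolerance),
        "weight": float(f.weight),
        "provenance": [[c, int(n)] for c, n in f.provenance],
    }


def _feature_from_dict(d: dict) -> PharmacophoreFeature:
    return PharmacophoreFeature(
        kind=d["kind"],
        position=np.array(d["position"], dtype=float),
        direction=None if d["direction"] is None else np.array(d["direction"], dtype=float),
        tolerance=float(d["tolerance"]),
        weight=float(d["weight"]),
        provenance=[(c, int(n)) for c, n in d["provenance"]],
    )


def map_to_json(imap: InteractionMap) -> str:
    return json.dumps({
        "pocket": {"center": [float(x) for x in imap.pocket.center],
                   "radius": float(imap.pocket.radius)},
        "features": [_feature_to_dict(f) for f in imap.features],
        "exclusions": [{"center": [float(x) for x in e.center],
                        "radius": float(e.radius),
                        "source": [[e.source_atom[0][0], int(e.source_atom[0][1])],
                                   e.source_atom[1]]}
                       for e in imap.exclusions],
    }, indent=1)


def map_from_json(text: str) -> InteractionMap:
    d = json.loads(text)
    pocket = PocketSphere(np.array(d["pocket"]["center"], float), float(d["pocket"]["radius"]))
    feats = [_feature_from_dict(f) for f in d["features"]]
    excl = [ExclusionVolume(np.array(e["center"], float), float(e["radius"]),
                            ((e["source"][0][0], int(e["source"][0][1])), e["source"][1]))
            for e in d["exclusions"]]
    return InteractionMap(features=feats, exclusions=excl, pocket=pocket)
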
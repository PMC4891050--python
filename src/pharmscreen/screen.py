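"""The virtual-screening funnel: filters, matching, alignment, fit, ranking.

A library is first reduced by physicochemical property filters (MW, logP,
logS), then every surviving ligand conformer is matched against every query
hypothesis.  Matching searches injective, kind-compatible assignments of
hypothesis features to ligand features, pruned by pairwise-distance
compatibility; each surviving assignment is realized in 3D by a proper-rotation
Kabsch superposition of the matched ligand feature points onto the hypothesis
points, rejected if any heavy atom penetrates an exclusion volume, and scored

    fit = sum_i w_i * max(0, 1 - (d_i / t_i)^2)

where d_i is the residual distance of hypothesis feature i to its matched
ligand feature and t_i its tolerance sphere.  The fit is maximal (sum of
weights) at perfect superposition and a feature stops contributing once its
residual reaches its tolerance.  The funnel then proceeds best-fit cut ->
energy rescoring cut -> diversity selection, with sizes mirroring the original
campaign (5000 -> 1000 -> 100) but configurable for desk-scale runs.

Every stage is deterministic: ties are broken by ligand id ascending, then
hypothesis id, then conformer index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imap import ExclusionVolume, Hypothesis
from .ligands import Fingerprint, Ligand, LigandFeature, compute_properties, tanimoto

__all__ = [
    "MatchResult",
    "FunnelReport",
    "property_filter",
    "match_features",
    "kabsch",
    "align_pose",
    "fit_score",
    "exclusion_check",
    "screen_library",
    "select_top",
    "diversity_select",
]

MW_MAX = 500.0
LOGP_MAX = 5.0
LOGS_MIN = -6.0


@dataclass
class MatchResult:
    ligand_id: str
    hypothesis_id: str
    conformer_index: int
    mapping: tuple[int, ...]  # mapping[i] = ligand feature index matched to hypothesis feature i
    fit: float
    pose: np.ndarray  # transformed conformer coordinates, (n_atoms, 3)
    pose_features: list[LigandFeature] = field(default_factory=list)


@dataclass
class FunnelReport:
    counts: dict[str, int] = field(default_factory=dict)
    ranked_ids: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, ids: list[str]) -> None:
        self.counts[stage] = len(ids)
        self.ranked_ids[stage] = list(ids)

    def to_tsv(self) -> str:
        rows = ["stage\tcount\tids"]
        for stage, count in self.counts.items():
            rows.append(f"{stage}\t{count}\t{','.join(self.ranked_ids[stage])}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Property filter
# ---------------------------------------------------------------------------

def property_filter(library: list[Ligand], mw_max: float = MW_MAX,
                    logp_max: float = LOGP_MAX, logs_min: float = LOGS_MIN) -> list[Ligand]:
    """Keep ligands with mw <= mw_max, logp <= logp_max, logs >= logs_min.

    Boundaries are inclusive; input order preserved.
    """
    out = []
    for lig in library:
        p = lig.properties or compute_properties(lig)
        if p.mw <= mw_max and p.logp <= logp_max and p.logs >= logs_min:
            out.append(lig)
    return out


# ---------------------------------------------------------------------------
# Feature matching
# ---------------------------------------------------------------------------

def match_features(ligand_features: list[LigandFeature], hypothesis: Hypothesis,
                   tolerances: list[float] | None = None) -> list[tuple[int, ...]]:
    """All injective kind-compatible assignments passing the distance prune.

    Assignment `m` maps hypothesis feature i to ligand feature m[i]; for every
    already-assigned pair (i, j) the prune requires
    |d_lig(m[i], m[j]) - d_hyp(i, j)| <= t_i + t_j.  Results are emitted in
    lexicographic order of the chosen ligand indices.
    """
    k = len(hypothesis.features)
    if tolerances is None:
        tolerances = [f.tolerance for f in hypothesis.features]
    hyp_pos = hypothesis.positions
    hyp_dist = np.linalg.norm(hyp_pos[:, None, :] - hyp_pos[None, :, :], axis=2)
    lig_pos = np.array([f.position for f in ligand_features], dtype=float).reshape(-1, 3)
    n = len(ligand_features)
    lig_dist = (np.linalg.norm(lig_pos[:, None, :] - lig_pos[None, :, :], axis=2)
                if n else np.zeros((0, 0)))
    candidates = [
        [j for j in range(n) if ligand_features[j].kind == hypothesis.features[i].kind]
        for i in range(k)
    ]
    results: list[tuple[int, ...]] = []
    assignment: list[int] = []
    used: set[int] = set()

    def backtrack(i: int) -> None:
        if i == k:
            results.append(tuple(assignment))
            return
        for j in candidates[i]:
            if j in used:
                continue
            ok = True
            for prev_i, prev_j in enumerate(assignment):
                if abs(lig_dist[j, prev_j] - hyp_dist[i, prev_i]) > tolerances[i] + tolerances[prev_i]:
                    ok = False
                    break
            if ok:
                assignment.append(j)
                used.add(j)
                backtrack(i + 1)
                assignment.pop()
                used.discard(j)

    backtrack(0)
    return results


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with
    ``mobile @ R.T + t ~= target``; reflections are never returned."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def align_pose(conformer: np.ndarray, mapping: tuple[int, ...],
               ligand_features: list[LigandFeature],
               hypothesis: Hypothesis) -> np.ndarray:
    """Rigidly superpose matched ligand feature points onto the hypothesis and
    transform the whole conformer."""
    if len(mapping) < 3:
        raise ValueError("alignment needs >= 3 matched points")
    src = np.array([ligand_features[j].position for j in mapping], dtype=float)
    dst = hypothesis.positions
    R, t = kabsch(src, dst)
    return np.asarray(conformer, float) @ R.T + t


def _transform_features(features: list[LigandFeature], R: np.ndarray,
                        t: np.ndarray) -> list[LigandFeature]:
    return [LigandFeature(f.kind, R @ f.position + t, f.atom_indices) for f in features]


# ---------------------------------------------------------------------------
# Scoring and constraint checks
# ---------------------------------------------------------------------------

def fit_score(pose_feature_positions: np.ndarray, hypothesis: Hypothesis) -> float:
    """Quadratic-falloff fit of matched (aligned) feature points to the query.

    ``pose_feature_positions[i]`` is the aligned ligand feature matched to
    hypothesis feature i.
    """
    total = 0.0
    for i, f in enumerate(hypothesis.features):
        d = float(np.linalg.norm(np.asarray(pose_feature_positions[i], float) - f.position))
        total += f.weight * max(0.0, 1.0 - (d / f.tolerance) ** 2)
    return total


def exclusion_check(pose: np.ndarray, heavy_mask: np.ndarray,
                    exclusions: list[ExclusionVolume]) -> tuple[bool, int | None]:
    """(passed, first_violating_atom_index); an atom fails only strictly inside
    an exclusion sphere (surface contact passes)."""
    pose = np.asarray(pose, float)
    heavy_idx = np.nonzero(np.asarray(heavy_mask, bool))[0]
    for excl in exclusions:
        d = np.linalg.norm(pose[heavy_idx] - excl.center, axis=1)
        inside = d < excl.radius
        if np.any(inside):
            return False, int(heavy_idx[int(np.argmax(inside))])
    return True, None


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _heavy_mask(ligand: Ligand) -> np.ndarray:
    return np.array([a.GetSymbol() not in ("H", "D") for a in ligand.mol.GetAtoms()],
                    dtype=bool)


def screen_library(library: list[Ligand], hypotheses: list[Hypothesis],
                   exclusions: list[ExclusionVolume],
                   report: FunnelReport | None = None) -> list[MatchResult]:
    """Best exclusion-passing match per ligand, ranked by fit descending.

    For each ligand the best (maximum-fit) result over all hypotheses,
    conformers and assignments is retained; ligands with no complete,
    exclusion-passing match are dropped.  Fully deterministic.
    """
    from .ligands import perceive_ligand_features

    results: list[MatchResult] = []
    for lig in sorted(library, key=lambda L: L.id):
        heavy = _heavy_mask(lig)
        best: MatchResult | None = None
        for hyp in sorted(hypotheses, key=lambda h: h.id):
            for conf in range(lig.n_conformers):
                feats = perceive_ligand_features(lig, conf)
                coords = lig.conformer_coords(conf)
                for mapping in match_features(feats, hyp):
                    src = np.array([feats[j].position for j in mapping], dtype=float)
                    R, t = kabsch(src, hyp.positions)
                    pose = coords @ R.T + t
                    ok, _ = exclusion_check(pose, heavy, exclusions)
                    if not ok:
                        continue
                    aligned = src @ R.T + t
                    fit = fit_score(aligned, hyp)
                    if best is None or fit > best.fit:
                        best = MatchResult(
                            ligand_id=lig.id, hypothesis_id=hyp.id,
                            conformer_index=conf, mapping=mapping, fit=fit,
                            pose=pose,
                            pose_features=_transform_features(feats, R, t),
                        )
        if best is not None:
            results.append(best)
    results.sort(key=lambda r: (-r.fit, r.ligand_id))
    if report is not None:
        report.record("matched", [r.ligand_id for r in results])
    return results


def select_top(ranked: list, n: int) -> list:
    """First min(n, len) entries of an already-ranked list."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return list(ranked[:n])


def diversity_select(ranked: list[MatchResult], fingerprints: dict[str, Fingerprint],
                     n: int, sim_threshold: float = 0.9) -> list[MatchResult]:
    """Leader selection in rank order: accept a candidate iff its Tanimoto
    similarity to every accepted leader is < sim_threshold; stop at n."""
    leaders: list[MatchResult] = []
    for cand in ranked:
        if len(leaders) >= n:
            break
        fp = fingerprints[cand.ligand_id]
        if all(tanimoto(fp, fingerprints[l.ligand_id]) < sim_threshold for l in leaders):
            leaders.append(cand)
    return leaders
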
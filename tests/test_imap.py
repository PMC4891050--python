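"""Interaction-map generation, clustering and hypothesis enumeration."""

import itertools
import math

import numpy as np
import pytest

from pharmscreen import (
    PocketSphere, cluster_features, complement_features, enumerate_hypotheses,
    exclusion_volumes, map_from_json, map_to_json, perceive_sites,
)
from pharmscreen.imap import (ACCEPTOR, D_HB, DONOR, HYDROPHOBIC,
                              PharmacophoreFeature, ProteinSite)
from pharmscreen.structure import Atom, ProteinStructure, Residue


def feature(kind, pos, tol=1.5, weight=1.0, direction=None):
    return PharmacophoreFeature(kind=kind, position=np.asarray(pos, float),
                                direction=direction, tolerance=tol, weight=weight)


# ---------------------------------------------------------------------------
# Site perception
# ---------------------------------------------------------------------------

class TestPerceiveSites:
    def test_glutamate_side_chain_gives_oe_acceptors(self, toy_structure):
        glu = toy_structure.residue("A", 64)
        sites = perceive_sites([glu])
        acceptor_atoms = {s.atom_name for s in sites if s.kind == ACCEPTOR}
        assert {"OE1", "OE2"} <= acceptor_atoms

    def test_glycine_backbone_only(self, toy_structure):
        gly = toy_structure.residue("A", 71)
        sites = perceive_sites([gly])
        assert {(s.kind, s.atom_name) for s in sites} == {(DONOR, "N"), (ACCEPTOR, "O")}

    def test_empty_list(self):
        assert perceive_sites([]) == []

    def test_directions_are_unit_vectors(self, toy_structure):
        for s in perceive_sites(toy_structure.residues):
            if s.direction is not None:
                assert np.linalg.norm(s.direction) == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Complementary feature placement
# ---------------------------------------------------------------------------

def _bare_structure(positions):
    res = Residue(name="ALA", number=1, chain="A",
                  atoms=[Atom("CB", "C", np.asarray(p, float), i + 1)
                         for i, p in enumerate(positions)])
    return ProteinStructure(id="bare", residues=[res])


class TestComplementFeatures:
    def test_donor_projects_acceptor_along_direction(self):
        u = np.array([1.0, 0.0, 0.0])
        site = ProteinSite(DONOR, np.zeros(3), u, ("A", 1), "N")
        pocket = PocketSphere(np.array([5.0, 0, 0]), 8.0)
        feats = complement_features([site], _bare_structure([[-3, 0, 0]]), pocket)
        assert len(feats) == 1
        assert feats[0].kind == ACCEPTOR
        np.testing.assert_allclose(feats[0].position, D_HB * u, atol=1e-12)

    def test_clashing_projection_is_discarded(self):
        u = np.array([1.0, 0.0, 0.0])
        site = ProteinSite(DONOR, np.zeros(3), u, ("A", 1), "N")
        pocket = PocketSphere(np.array([5.0, 0, 0]), 8.0)
        # protein atom 1.0 A from the projected point; clash_dist 1.5 kills it
        blocker = _bare_structure([[D_HB + 1.0, 0.0, 0.0]])
        assert complement_features([site], blocker, pocket) == []

    def test_toy_pocket_counts_match_manual_projection(self, toy_structure,
                                                       pocket_sphere):
        """Independent re-derivation: project every site by the placement rules
        and count survivors of the pocket/clash filters."""
        sites = perceive_sites(toy_structure.residues)
        protein = toy_structure.heavy_coords()
        expected = 0
        for s in sites:
            if s.kind == HYDROPHOBIC:
                d = 4.0
                v = pocket_sphere.center - s.position
                direction = v / np.linalg.norm(v)
            else:
                d = D_HB
                direction = s.direction
                if direction is None:
                    v = pocket_sphere.center - s.position
                    direction = v / np.linalg.norm(v)
            p = s.position + d * direction
            if np.linalg.norm(p - pocket_sphere.center) > pocket_sphere.radius:
                continue
            if np.min(np.linalg.norm(protein - p, axis=1)) < 1.5:
                continue
            expected += 1
        got = complement_features(sites, toy_structure, pocket_sphere)
        assert len(got) == expected


class TestExclusionVolumes:
    def test_single_atom_inside_pocket(self):
        s = _bare_structure([[0.0, 0.0, 0.0]])
        vols = exclusion_volumes(s, PocketSphere(np.zeros(3), 5.0), margin=0.0)
        assert len(vols) == 1
        np.testing.assert_allclose(vols[0].center, np.zeros(3))

    def test_margin_monotonicity(self, toy_structure, pocket_sphere):
        n0 = len(exclusion_volumes(toy_structure, pocket_sphere, margin=0.0))
        n5 = len(exclusion_volumes(toy_structure, pocket_sphere, margin=5.0))
        assert n0 <= n5

    def test_centers_match_distance_scan(self, toy_structure, pocket_sphere):
        margin = 2.0
        expected = [a.position for _, a in toy_structure.heavy_atoms()
                    if np.linalg.norm(a.position - pocket_sphere.center)
                    <= pocket_sphere.radius + margin]
        got = exclusion_volumes(toy_structure, pocket_sphere, margin=margin)
        assert len(got) == len(expected)
        for vol, pos in zip(got, expected):
            np.testing.assert_allclose(vol.center, pos)


# ---------------------------------------------------------------------------
# Clustering: naive complete-linkage oracle
# ---------------------------------------------------------------------------

def _naive_linkage_pass(items, cutoff):
    """One brute-force complete-linkage agglomeration: repeatedly merge the
    closest pair of clusters (max inter-point distance) while <= cutoff.
    `items` is a list of (point, member_set, weight)."""
    clusters = [[i] for i in range(len(items))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(np.linalg.norm(items[i][0] - items[j][0])
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        if best is None or best[0] > cutoff:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    out = []
    for c in clusters:
        w = sum(items[i][2] for i in c)
        pos = sum(items[i][0] * items[i][2] for i in c) / w
        members = frozenset().union(*(items[i][1] for i in c))
        out.append((pos, members, w))
    return out


def naive_complete_linkage(points, cutoff):
    """Iterated brute-force complete-linkage condensation (to a fixed point,
    with weight-averaged representatives), mirroring the declared algorithm."""
    items = [(np.asarray(p, float), frozenset({i}), 1.0)
             for i, p in enumerate(points)]
    while True:
        merged = _naive_linkage_pass(items, cutoff)
        if len(merged) == len(items):
            return sorted(m for _, m, _ in merged)
        items = merged


def cluster_membership(features, clustered):
    """Recover member sets by provenance bookkeeping (unique tags)."""
    out = []
    for cf in clustered:
        out.append(frozenset(int(p[1]) for p in cf.provenance))
    return sorted(out)


class TestClusterFeatures:
    def test_coincident_pair_merges_with_weight_two(self):
        feats = [feature(ACCEPTOR, [1, 2, 3]), feature(ACCEPTOR, [1, 2, 3])]
        out = cluster_features(feats, cutoff=1.5)
        assert len(out) == 1
        assert out[0].weight == pytest.approx(2.0)
        np.testing.assert_allclose(out[0].position, [1, 2, 3])

    def test_distant_pair_retained(self):
        feats = [feature(ACCEPTOR, [0, 0, 0]), feature(ACCEPTOR, [10, 0, 0])]
        out = cluster_features(feats, cutoff=1.5)
        assert len(out) == 2

    def test_kinds_never_merge(self):
        feats = [feature(ACCEPTOR, [0, 0, 0]), feature(DONOR, [0, 0, 0])]
        assert len(cluster_features(feats, cutoff=1.5)) == 2

    def test_collinear_example_matches_oracle(self):
        xs = [0.0, 1.0, 2.0, 8.0, 9.0]
        feats = [PharmacophoreFeature(ACCEPTOR, np.array([x, 0.0, 0.0]),
                                      provenance=[("A", i)])
                 for i, x in enumerate(xs)]
        out = cluster_features(feats, cutoff=2.5)
        got = cluster_membership(feats, out)
        assert got == [frozenset({0, 1, 2}), frozenset({3, 4})]
        points = [f.position for f in feats]
        assert got == naive_complete_linkage(points, 2.5)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_sets_match_oracle_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        pts = rng.uniform(-5, 5, size=(n, 3))
        feats = [PharmacophoreFeature(ACCEPTOR, pts[i], provenance=[("A", i)])
                 for i in range(n)]
        cutoff = float(rng.uniform(1.0, 6.0))
        out = cluster_features(feats, cutoff)
        assert cluster_membership(feats, out) == naive_complete_linkage(pts, cutoff)
        # weight conservation
        assert sum(f.weight for f in out) == pytest.approx(n)
        # idempotence
        again = cluster_features(out, cutoff)
        assert len(again) == len(out)
        for f1, f2 in zip(out, again):
            np.testing.assert_allclose(f1.position, f2.position)
            assert f1.weight == pytest.approx(f2.weight)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cluster_features([feature(ACCEPTOR, [0, 0, 0])], cutoff=0.0)


# ---------------------------------------------------------------------------
# Hypothesis enumeration
# ---------------------------------------------------------------------------

def brute_force_subsets(features, kmin, kmax, min_pair_dist):
    pos = [f.position for f in features]
    out = []
    for k in range(kmin, kmax + 1):
        for combo in itertools.combinations(range(len(features)), k):
            if all(np.linalg.norm(pos[i] - pos[j]) >= min_pair_dist
                   for i, j in itertools.combinations(combo, 2)):
                out.append(combo)
    return out


class TestEnumerateHypotheses:
    def test_seven_unconstrained_features_give_99(self):
        rng = np.random.default_rng(0)
        feats = [feature(ACCEPTOR, rng.uniform(-9, 9, 3)) for _ in range(7)]
        hyps = enumerate_hypotheses(feats, 3, 7, min_pair_dist=0.0)
        assert len(hyps) == sum(math.comb(7, k) for k in range(3, 8)) == 99

    def test_close_pair_constraint_matches_brute_force(self):
        feats = [feature(DONOR, [0, 0, 0]), feature(DONOR, [0.5, 0, 0]),
                 feature(ACCEPTOR, [5, 0, 0]), feature(HYDROPHOBIC, [0, 5, 0]),
                 feature(ACCEPTOR, [0, 0, 5])]
        hyps = enumerate_hypotheses(feats, 3, 5, min_pair_dist=2.0)
        expected = brute_force_subsets(feats, 3, 5, 2.0)
        got = [tuple(int(t) for t in h.id.split("-")) for h in hyps]
        assert got == expected
        # the 0.5-A pair never appears together
        assert all(not ({0, 1} <= set(c)) for c in got)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        feats = [feature(ACCEPTOR, rng.uniform(-6, 6, 3))
                 for _ in range(int(rng.integers(4, 9)))]
        mpd = float(rng.uniform(0.0, 5.0))
        got = [tuple(int(t) for t in h.id.split("-"))
               for h in enumerate_hypotheses(feats, 3, 7, mpd)]
        assert got == brute_force_subsets(feats, 3, min(7, len(feats)), mpd)

    def test_too_few_features_empty(self):
        feats = [feature(DONOR, [0, 0, 0]), feature(ACCEPTOR, [4, 0, 0])]
        assert enumerate_hypotheses(feats, 3, 7) == []

    def test_every_hypothesis_feature_is_a_map_member(self, interaction_map):
        hyps = enumerate_hypotheses(interaction_map.features[:8], 3, 4)
        members = {id(f) for f in interaction_map.features}
        for h in hyps:
            for f in h.features:
                assert id(f) in members


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_map_json_round_trip(interaction_map):
    again = map_from_json(map_to_json(interaction_map))
    assert len(again.features) == len(interaction_map.features)
    assert len(again.exclusions) == len(interaction_map.exclusions)
    for f1, f2 in zip(interaction_map.features, again.features):
        assert f1.kind == f2.kind
        np.testing.assert_allclose(f1.position, f2.position, atol=1e-6)
        assert f1.weight == pytest.approx(f2.weight, abs=1e-6)
        assert f1.provenance == f2.provenance
    np.testing.assert_allclose(
        [e.center for e in again.exclusions],
        [e.center for e in interaction_map.exclusions], atol=1e-6)


def test_map_features_lie_inside_pocket(interaction_map):
    pocket = interaction_map.pocket
    for f in interaction_map.features:
        assert np.linalg.norm(f.position - pocket.center) <= pocket.radius + 2.0
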
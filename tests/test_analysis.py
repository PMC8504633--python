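"""SASA, contact maps/order, salt bridges, H-bonds and hydrophobic clusters."""

import itertools
import math

import numpy as np
import pytest

from chimeraforge import build_ideal_ss
from chimeraforge.analysis import (
    VDW_RADII,
    contact_map,
    contact_order,
    hbonds,
    hydrophobic_clusters,
    report,
    salt_bridges,
    sasa,
)
from chimeraforge.structures import Atom, Residue, Structure

from conftest import random_rotation


def point_residue(name3, coords_by_atom, resid=1, chain="A"):
    atoms = [Atom(i + 1, name, name[0], np.asarray(c, float))
             for i, (name, c) in enumerate(coords_by_atom.items())]
    return Residue(name3, chain, resid, "", atoms)


def lys_asp_pair(o_to_n: float) -> Structure:
    """Asp carboxylate O placed ``o_to_n`` Å from a Lys NZ, backbones apart."""
    asp = point_residue("ASP", {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0), "O": (1.7, 2.4, 0),
        "CB": (2.2, -1.2, 0), "CG": (3.7, -1.2, 0),
        "OD1": (4.3, -0.1, 0), "OD2": (4.3, -2.3, 0),
    }, resid=1)
    base = np.array([4.3, -0.1, 0.0])
    nz = base + np.array([o_to_n, 0, 0])
    lys = point_residue("LYS", {
        "N": tuple(nz + (8, 0, 0)), "CA": tuple(nz + (7, 1, 0)),
        "C": tuple(nz + (6, 2, 0)), "O": tuple(nz + (6.5, 3, 0)),
        "CB": tuple(nz + (5, 0, 0)), "CG": tuple(nz + (4, 0, 0)),
        "CD": tuple(nz + (3, 0, 0)), "CE": tuple(nz + (1.5, 0, 0)),
        "NZ": tuple(nz),
    }, resid=2)
    return Structure("sb", [asp, lys])


def leu_residue(center, resid):
    c = np.asarray(center, float)
    return point_residue("LEU", {
        "N": tuple(c + (-2, 2, 0)), "CA": tuple(c + (-1, 1.5, 0)),
        "C": tuple(c + (0, 2.5, 0)), "O": tuple(c + (1, 3, 0)),
        "CB": tuple(c + (0, 0, 0)), "CG": tuple(c + (1.2, -0.6, 0)),
        "CD1": tuple(c + (2.4, 0.2, 0)), "CD2": tuple(c + (1.4, -2.0, 0)),
    }, resid=resid)


class TestSasa:
    def test_isolated_carbon_analytic_sphere(self):
        s = Structure("c", [point_residue("ALA", {"CB": (0, 0, 0)})])
        total, per_res = sasa(s)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)
        assert per_res.sum() == pytest.approx(total)

    def test_distant_atoms_additive(self):
        s = Structure("cc", [
            point_residue("ALA", {"CB": (0, 0, 0)}, resid=1),
            point_residue("ALA", {"CB": (100, 0, 0)}, resid=2),
        ])
        total, per_res = sasa(s)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(2 * analytic, rel=0.01)
        assert per_res[0] == pytest.approx(per_res[1], rel=1e-9)

    def test_overlapping_spheres_share_one_envelope(self):
        near, _ = sasa(Structure("h", [
            point_residue("ALA", {"CB": (0, 0, 0)}, resid=1),
            point_residue("ALA", {"CB": (0.0, 0, 0.01)}, resid=2),
        ]))
        lone, _ = sasa(Structure("l", [point_residue("ALA", {"CB": (0, 0, 0)})]))
        # Two near-coincident spheres expose two half-spheres: one envelope.
        assert near == pytest.approx(lone, rel=0.02)

    def test_self_convergence_on_helix(self, helix12):
        coarse, _ = sasa(helix12, n_sphere_points=960)
        fine, _ = sasa(helix12, n_sphere_points=10000)
        assert abs(coarse - fine) / fine <= 0.02

    def test_unknown_element_falls_back(self):
        s = Structure("x", [point_residue("ALA", {"XX": (0, 0, 0)})])
        with pytest.warns(UserWarning, match="fallback"):
            total, _ = sasa(s)
        assert total == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.01)


class TestContactMap:
    def test_two_residue_matrix(self):
        s = Structure("two", [
            point_residue("GLY", {"CA": (0, 0, 0)}, resid=1),
            point_residue("GLY", {"CA": (3.8, 0, 0)}, resid=2),
        ])
        cm = contact_map(s)
        assert np.allclose(cm.matrix, [[0, 3.8], [3.8, 0]])

    def test_symmetry_zero_diagonal(self, mixed_chain):
        m = contact_map(mixed_chain).matrix
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_helix_i_i4_distance(self, helix12):
        m = contact_map(helix12).matrix
        d = np.array([m[i, i + 4] for i in range(len(helix12) - 4)])
        assert np.all(np.abs(d - 6.2) < 0.5)

    def test_missing_ca_named(self):
        s = Structure("no_ca", [point_residue("GLY", {"N": (0, 0, 0)}, resid=7)])
        with pytest.raises(ValueError, match="7"):
            contact_map(s)


class TestContactOrder:
    def test_closed_form_three_residues(self):
        s = Structure("t", [
            point_residue("GLY", {"CA": (0, 0, 0)}, resid=1),
            point_residue("GLY", {"CA": (50, 0, 0)}, resid=2),
            point_residue("GLY", {"CA": (4, 0, 0)}, resid=3),
        ])
        # Only the (0, 2) pair is within 6 Å: RCO = 100 * 2 / (3 * 1).
        assert contact_order(s) == pytest.approx(100 * 2 / 3)

    def test_rigid_motion_invariant(self, mixed_chain):
        base = contact_order(mixed_chain)
        rng = np.random.default_rng(11)
        rot = random_rotation(rng)
        moved = mixed_chain.transformed(rot, rng.uniform(-50, 50, 3))
        assert contact_order(moved) == pytest.approx(base, rel=1e-9)

    def test_matches_brute_force_on_helix(self, helix12):
        coords = [(i, a.coords) for i, r in enumerate(helix12.residues)
                  for a in r.atoms]
        pairs = set()
        for (i, ci), (j, cj) in itertools.combinations(coords, 2):
            if abs(i - j) >= 1 and np.linalg.norm(ci - cj) < 6.0:
                pairs.add((min(i, j), max(i, j)))
        expected = 100 * sum(j - i for i, j in pairs) / (len(helix12) * len(pairs))
        assert contact_order(helix12) == pytest.approx(expected)

    def test_no_contacts_is_error(self):
        s = Structure("far", [
            point_residue("GLY", {"CA": (0, 0, 0)}, resid=1),
            point_residue("GLY", {"CA": (100, 0, 0)}, resid=2),
        ])
        with pytest.raises(ValueError, match="undefined|contact"):
            contact_order(s)


class TestSaltBridges:
    def test_bridge_at_3_5(self):
        found = salt_bridges(lys_asp_pair(3.5))
        assert len(found) == 1
        assert found[0].min_distance == pytest.approx(3.5)
        assert (found[0].acidic_name3, found[0].basic_name3) == ("ASP", "LYS")

    def test_no_bridge_at_4_5(self):
        assert salt_bridges(lys_asp_pair(4.5)) == []

    def test_pair_deduplicated_to_min_distance(self):
        s = lys_asp_pair(3.5)
        # Both OD1 and OD2 within cutoff: still one record, min distance kept.
        asp = s.residues[0]
        od2 = asp.atom("OD2")
        nz = s.residues[1].atom("NZ").coords
        moved = [a if a.name != "OD2"
                 else Atom(a.serial, a.name, a.element, nz + (0, 3.0, 0))
                 for a in asp.atoms]
        s2 = Structure("sb2", [Residue("ASP", "A", 1, "", moved), s.residues[1]])
        found = salt_bridges(s2)
        assert len(found) == 1
        assert found[0].min_distance == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        residues = []
        for i in range(12):
            center = rng.uniform(-12, 12, 3)
            kind = rng.choice(["ASP", "LYS", "ALA"])
            if kind == "ASP":
                residues.append(point_residue("ASP", {
                    "N": tuple(center), "CA": tuple(center + (1.5, 0, 0)),
                    "OD1": tuple(center + rng.uniform(-2, 2, 3)),
                    "OD2": tuple(center + rng.uniform(-2, 2, 3)),
                }, resid=i + 1))
            elif kind == "LYS":
                residues.append(point_residue("LYS", {
                    "N": tuple(center), "CA": tuple(center + (1.5, 0, 0)),
                    "NZ": tuple(center + rng.uniform(-2, 2, 3)),
                }, resid=i + 1))
            else:
                residues.append(point_residue("ALA", {
                    "N": tuple(center), "CA": tuple(center + (1.5, 0, 0)),
                }, resid=i + 1))
        s = Structure(f"rand{seed}", residues)
        found = {(sb.acidic_index, sb.basic_index) for sb in salt_bridges(s)}
        expected = set()
        for i, ri in enumerate(residues):
            for j, rj in enumerate(residues):
                if ri.name3 == "ASP" and rj.name3 == "LYS":
                    d = min(np.linalg.norm(ri.atom(o).coords - rj.atom("NZ").coords)
                            for o in ("OD1", "OD2"))
                    if d < 4.0:
                        expected.add((i, j))
        assert found == expected


class TestHbonds:
    def test_helix_backbone_ladder(self, helix12):
        found = hbonds(helix12)
        pairs = {(d, a) for d, a, _ in found}
        # The i+4 -> i backbone ladder of an ideal helix.
        for i in range(len(helix12) - 4):
            assert (i + 4, i) in pairs

    def test_distant_glycines_empty(self):
        s = Structure("fg", [
            point_residue("GLY", {"N": (0, 0, 0), "O": (1, 0, 0)}, resid=1),
            point_residue("GLY", {"N": (20, 0, 0), "O": (21, 0, 0)}, resid=2),
        ])
        assert hbonds(s) == []

    def test_zero_cutoff_empty(self, helix12):
        assert hbonds(helix12, d_max=0.0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random_fixtures(self, seed):
        rng = np.random.default_rng(100 + seed)
        residues = []
        for i in range(10):
            c = rng.uniform(-8, 8, 3)
            residues.append(point_residue("GLY", {
                "N": tuple(c), "CA": tuple(c + (1.4, 0, 0)),
                "C": tuple(c + (2.1, 1.2, 0)), "O": tuple(c + rng.uniform(-2, 2, 3)),
            }, resid=i + 1))
        s = Structure(f"hb{seed}", residues)
        found = {(d, a) for d, a, _ in hbonds(s)}
        expected = set()
        for i, ri in enumerate(residues):
            for j, rj in enumerate(residues):
                if i == j or abs(i - j) < 2:
                    continue
                if np.linalg.norm(ri.atom("N").coords - rj.atom("O").coords) < 3.5:
                    expected.add((i, j))
        assert found == expected


class TestHydrophobicClusters:
    def test_interdigitated_leucine_pair(self):
        s = Structure("ll", [leu_residue((0, 0, 0), 1),
                             leu_residue((3.5, -1.5, 0.5), 2)])
        clusters = hydrophobic_clusters(s, min_cluster_size=2)
        assert len(clusters) == 1
        assert clusters[0].residue_indices == frozenset({0, 1})
        assert clusters[0].area > 0

    def test_far_pair_no_cluster(self):
        s = Structure("ll", [leu_residue((0, 0, 0), 1),
                             leu_residue((15, 0, 0), 2)])
        assert hydrophobic_clusters(s, min_cluster_size=2) == []

    def test_transitive_chain_single_cluster(self):
        # A-B and B-C in contact, A-C not: one 3-residue cluster.
        s = Structure("abc", [leu_residue((0, 0, 0), 1),
                              leu_residue((4.5, 0, 0), 2),
                              leu_residue((9.0, 0, 0), 3)])
        clusters = hydrophobic_clusters(s, min_cluster_size=2)
        assert len(clusters) == 1
        assert clusters[0].residue_indices == frozenset({0, 1, 2})

    def test_min_cluster_size_filters(self):
        s = Structure("ll", [leu_residue((0, 0, 0), 1),
                             leu_residue((3.5, -1.5, 0.5), 2)])
        assert hydrophobic_clusters(s, min_cluster_size=4) == []

    def test_polar_residues_ignored(self):
        ser = point_residue("SER", {"CB": (2, 0, 0), "OG": (3, 0, 0)}, resid=2)
        s = Structure("ls", [leu_residue((0, 0, 0), 1), ser])
        assert hydrophobic_clusters(s, min_cluster_size=2) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random_fixtures(self, seed):
        rng = np.random.default_rng(200 + seed)
        residues = [leu_residue(tuple(rng.uniform(-14, 14, 3)), i + 1)
                    for i in range(10)]
        s = Structure(f"hc{seed}", residues)
        clusters = hydrophobic_clusters(s, min_cluster_size=2)
        # Brute-force apolar contact graph + union-find over residues.
        from conftest import UnionFind

        apolar = [(i, a) for i, r in enumerate(residues) for a in r.atoms
                  if a.name not in ("N", "CA", "C", "O") and a.element in ("C", "S")]
        uf = UnionFind(range(len(residues)))
        linked = set()
        for (i, ai), (j, aj) in itertools.combinations(apolar, 2):
            if i == j:
                continue
            cut = VDW_RADII[ai.element] + VDW_RADII[aj.element] + 2 * 1.4
            if np.linalg.norm(ai.coords - aj.coords) <= cut:
                uf.union(i, j)
                linked.update((i, j))
        expected = {frozenset(g) for g in uf.partition()
                    if len(g) >= 2 and g <= linked}
        assert {c.residue_indices for c in clusters} == expected

    def test_rigid_motion_invariant_sizes(self):
        s = Structure("abc", [leu_residue((0, 0, 0), 1),
                              leu_residue((4.5, 0, 0), 2),
                              leu_residue((9.0, 0, 0), 3)])
        rng = np.random.default_rng(4)
        moved = s.transformed(random_rotation(rng), rng.uniform(-30, 30, 3))
        a = hydrophobic_clusters(s, min_cluster_size=2)
        b = hydrophobic_clusters(moved, min_cluster_size=2)
        assert [c.residue_indices for c in a] == [c.residue_indices for c in b]
        assert a[0].area == pytest.approx(b[0].area, rel=0.05)


class TestReport:
    def test_helix_report_complete(self, helix12):
        rec = report(helix12)
        for key in ("sasa_total", "relative_contact_order", "n_salt_bridges",
                    "n_hbonds", "hydrophobic_clusters"):
            assert key in rec
        assert rec["sasa_total"] > 0
        assert 0 < rec["relative_contact_order"] < 100
        import json

        json.dumps(rec)  # JSON-serialisable

    def test_partial_failure_does_not_abort(self):
        s = Structure("far", [
            point_residue("GLY", {"CA": (0, 0, 0)}, resid=1),
            point_residue("GLY", {"CA": (100, 0, 0)}, resid=2),
        ])
        rec = report(s)
        assert "error" in rec["relative_contact_order"]
        assert rec["n_salt_bridges"] == 0
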
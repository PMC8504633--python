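"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force or by a
different algorithm than the implementation (Horn's quaternion method vs
SVD Kabsch, union-find vs graph traversal, all-pairs scans vs KD-trees) so
that agreement is meaningful.
"""

from __future__ import annotations

import copy
import itertools

import numpy as np
import pytest

from chimeraforge import Structure, build_ideal_ss
from chimeraforge.hits import Hit


# ---------------------------------------------------------------------------
# Oracles


def horn_superpose(a: np.ndarray, b: np.ndarray):
    """Quaternion-eigenvalue (Horn) optimal superposition of b onto a.

    Independent of the SVD route: builds the 4x4 key matrix from the
    cross-covariance and takes the top eigenvector as the rotation
    quaternion.  Returns (rotation, translation, rmsd).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(0), b.mean(0)
    ac, bc = a - ca, b - cb
    m = bc.T @ ac
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(key)
    w, x, y, z = vecs[:, np.argmax(vals)]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted(groups.values(), key=lambda g: (-len(g), min(g)))


def brute_force_clash(chimera, d_clash: float) -> bool:
    """All-pairs backbone clash scan between parent halves, skipping
    chimera-adjacent residue pairs."""
    atoms = []
    for i, (res, tag) in enumerate(zip(chimera.structure.residues,
                                       chimera.provenance)):
        for a in res.atoms:
            if a.name in ("N", "CA", "C", "O"):
                atoms.append((i, tag, a.coords))
    for (i, ti, ci), (j, tj, cj) in itertools.combinations(atoms, 2):
        if ti == tj or abs(i - j) <= 1:
            continue
        if np.linalg.norm(ci - cj) < d_clash:
            return True
    return False


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation via QR with det correction."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture()
def helix12() -> Structure:
    return build_ideal_ss([("helix", 12)], "helix12")


@pytest.fixture()
def mixed_chain() -> Structure:
    return build_ideal_ss([("helix", 6), ("loop", 3), ("strand", 6)], "mixed")


def identical_parent_pair(spec=(("helix", 5), ("loop", 3), ("strand", 5))):
    """Two deep copies of one ideal chain plus an ungapped self-hit."""
    parent = build_ideal_ss(list(spec), "parent")
    q = Structure("q", copy.deepcopy(parent.residues))
    s = Structure("s", copy.deepcopy(parent.residues))
    L = len(parent)
    hit = Hit("q", "s", 1, 1, 0, L, 0, L, "A" * L, "A" * L,
              90.0, 0.0, 0.9, 100.0, "c.37.1.1", "c.2.1.1")
    return q, s, hit


@pytest.fixture()
def self_pair():
    return identical_parent_pair()
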
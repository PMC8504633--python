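"""Structural-analysis battery for parents and chimeras.

All detectors operate on heavy atoms only (the structures this package
handles — X-ray parents and freshly assembled chimeras — carry no
hydrogens), use simple geometric criteria, and are rigid-motion invariant.

* SASA — Shrake–Rupley sphere quadrature on a deterministic golden-spiral
  point set.
* Contact maps — full Cα–Cα distance matrices.
* Relative contact order — mean sequence separation of residue pairs in
  heavy-atom contact, normalised by chain length, in percent.
* Salt bridges — closest carboxylate-O to basic side-chain-N distance
  below a cutoff.
* Hydrogen bonds — heavy-atom N···O distance criterion.
* Hydrophobic clusters — connected components of the apolar side-chain
  contact graph, a distance-threshold approximation of contact-surface
  (CSU-style) cluster analysis, with summed pairwise contact-cap areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _sparse_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .structures import Structure

__all__ = [
    "ContactMap",
    "SaltBridge",
    "HydrophobicCluster",
    "sasa",
    "contact_map",
    "contact_order",
    "salt_bridges",
    "hbonds",
    "hydrophobic_clusters",
    "report",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
FALLBACK_RADIUS = 1.7
DEFAULT_PROBE = 1.4  # Å, water probe

ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}


def _radius(element: str) -> float:
    r = VDW_RADII.get(element)
    if r is None:
        warnings.warn(f"unknown element {element!r}: using fallback vdW radius "
                      f"{FALLBACK_RADIUS} Å", stacklevel=3)
        return FALLBACK_RADIUS
    return r


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack((
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ))


def sasa(s: Structure, probe: float = DEFAULT_PROBE,
         n_sphere_points: int = 960) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Each heavy atom's expanded sphere (r_vdw + probe) is sampled with a
    fixed golden-spiral point set; points buried inside any neighbour's
    expanded sphere are discarded.  Returns (total Å², per-residue Å²) with
    total == per-residue sum.
    """
    coords, radii, res_of = [], [], []
    for i, res in enumerate(s.residues):
        for a in res.atoms:
            coords.append(a.coords)
            radii.append(_radius(a.element))
            res_of.append(i)
    coords = np.asarray(coords)
    radii = np.asarray(radii) + probe
    unit = _sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    per_res = np.zeros(len(s.residues))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(c, r + radii.max()):
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - c)
            if d >= r + radii[j]:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not exposed.any():
                break
        area = 4.0 * np.pi * r**2 * exposed.sum() / n_sphere_points
        per_res[res_of[i]] += area
    return float(per_res.sum()), per_res


@dataclass(frozen=True)
class ContactMap:
    matrix: np.ndarray  # (L, L) Cα–Cα distances, Å
    contact_cutoff: float

    def contacts(self) -> np.ndarray:
        """Boolean contact matrix at the stored cutoff (diagonal False)."""
        mask = self.matrix < self.contact_cutoff
        np.fill_diagonal(mask, False)
        return mask


def contact_map(s: Structure, contact_cutoff: float = 8.0) -> ContactMap:
    """Full symmetric Cα–Cα distance matrix with zero diagonal."""
    ca = s.ca_coords()
    return ContactMap(squareform(pdist(ca)), contact_cutoff)


def contact_order(s: Structure, contact_dist: float = 6.0,
                  min_seq_sep: int = 1) -> float:
    """Relative contact order, percent: ``100 / (L * N) * sum(|i - j|)``
    over the N residue pairs with any heavy-atom pair within
    ``contact_dist`` and sequence separation >= ``min_seq_sep``."""
    L = len(s)
    if L < 2:
        raise ValueError("contact order needs at least 2 residues")
    coords, res_of = [], []
    for i, res in enumerate(s.residues):
        for a in res.atoms:
            coords.append(a.coords)
            res_of.append(i)
    coords = np.asarray(coords)
    res_of = np.asarray(res_of)
    tree = cKDTree(coords)
    pairs = set()
    for ai, aj in tree.query_pairs(contact_dist):
        ri, rj = int(res_of[ai]), int(res_of[aj])
        if abs(ri - rj) >= min_seq_sep:
            pairs.add((min(ri, rj), max(ri, rj)))
    if not pairs:
        raise ValueError("no residue contacts found; contact order undefined")
    total_sep = sum(j - i for i, j in pairs)
    return 100.0 * total_sep / (L * len(pairs))


@dataclass(frozen=True)
class SaltBridge:
    acidic_index: int
    basic_index: int
    acidic_name3: str
    basic_name3: str
    min_distance: float  # Å, closest carboxylate O to basic side-chain N


def salt_bridges(s: Structure, cutoff: float = 4.0) -> list[SaltBridge]:
    """Acidic/basic residue pairs whose closest carboxylate-O to side-chain-N
    distance (Asp OD1/2, Glu OE1/2 vs Lys NZ, Arg NE/NH1/NH2, His ND1/NE2)
    lies strictly below ``cutoff``; one record per residue pair."""
    acidic, basic = [], []
    for i, res in enumerate(s.residues):
        if res.name3 in ACIDIC_O:
            atoms = [res.atom(n) for n in ACIDIC_O[res.name3]]
            atoms = [a for a in atoms if a is not None]
            if not atoms:
                warnings.warn(f"{res.name3} {res.resid}: carboxylate atoms "
                              "missing; skipped", stacklevel=2)
                continue
            acidic.append((i, res.name3, np.array([a.coords for a in atoms])))
        elif res.name3 in BASIC_N:
            atoms = [res.atom(n) for n in BASIC_N[res.name3]]
            atoms = [a for a in atoms if a is not None]
            if not atoms:
                warnings.warn(f"{res.name3} {res.resid}: basic side-chain "
                              "nitrogens missing; skipped", stacklevel=2)
                continue
            basic.append((i, res.name3, np.array([a.coords for a in atoms])))

    out = []
    for ai, aname, acoords in acidic:
        for bi, bname, bcoords in basic:
            d = float(cdist(acoords, bcoords).min())
            if d < cutoff:
                out.append(SaltBridge(ai, bi, aname, bname, d))
    out.sort(key=lambda sb: (sb.acidic_index, sb.basic_index))
    return out


def hbonds(s: Structure, d_max: float = 3.5,
           use_angle: bool = False) -> list[tuple[int, int, float]]:
    """Heavy-atom hydrogen-bond detection: donor-N to acceptor-O pairs with
    distance strictly below ``d_max``.  Backbone–backbone pairs require a
    sequence separation of at least 2 (peptide neighbours are covalently
    constrained, not hydrogen-bonded).  ``use_angle`` is accepted for
    forward compatibility but ignored without hydrogens.

    Returns ``(donor_res_index, acceptor_res_index, distance)`` tuples.
    """
    if use_angle:
        warnings.warn("no hydrogens present: angle criterion ignored",
                      stacklevel=2)
    donors, acceptors = [], []
    for i, res in enumerate(s.residues):
        for a in res.atoms:
            if a.element == "N":
                donors.append((i, a.name, a.coords))
            elif a.element == "O":
                acceptors.append((i, a.name, a.coords))
    out = []
    for di, dname, dc in donors:
        for ai, aname, ac in acceptors:
            if di == ai:
                continue
            backbone_pair = dname == "N" and aname in ("O", "OXT")
            if backbone_pair and abs(di - ai) < 2:
                continue
            d = float(np.linalg.norm(dc - ac))
            if d < d_max:
                out.append((di, ai, d))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


@dataclass(frozen=True)
class HydrophobicCluster:
    residue_indices: frozenset[int]
    n_atoms: int
    area: float  # Å², summed pairwise contact-cap area

    @property
    def size(self) -> int:
        return len(self.residue_indices)


def _contact_cap_area(ci, ri, cj, rj, unit: np.ndarray, pad: float) -> float:
    """Contact area contribution of atom pair (i, j): the spherical cap of
    the smaller atom's padded sphere lying within the partner's padded
    sphere, estimated with the SASA quadrature."""
    if rj < ri:
        ci, ri, cj, rj = cj, rj, ci, ri
    pts = ci + (ri + pad) * unit
    inside = np.linalg.norm(pts - cj, axis=1) <= rj + pad
    return 4.0 * np.pi * (ri + pad) ** 2 * inside.sum() / len(unit)


def hydrophobic_clusters(s: Structure, contact_pad: float = DEFAULT_PROBE,
                         min_cluster_size: int = 4,
                         n_sphere_points: int = 960) -> list[HydrophobicCluster]:
    """Hydrophobic clusters as connected components of the apolar-contact
    graph.

    Apolar atoms are side-chain carbons and sulfurs of hydrophobic-class
    residues; two atoms are in contact when their centres lie within
    ``r_vdw(a) + r_vdw(b) + 2 * contact_pad`` (a solvent-pad relaxation of
    van-der-Waals contact standing in for the full contact-surface
    legitimacy test).  Residues joined by at least one atomic contact form
    clusters, filtered by ``min_cluster_size`` and sorted by residue count
    descending; each cluster's area sums the pairwise contact-cap areas of
    its atomic contacts.
    """
    coords, radii, res_of = [], [], []
    for i, res in enumerate(s.residues):
        if "hydrophobic" not in res.classes:
            continue
        for a in res.atoms:
            if a.name in ("N", "CA", "C", "O"):
                continue
            if a.element in ("C", "S"):
                coords.append(a.coords)
                radii.append(_radius(a.element))
                res_of.append(i)
    if not coords:
        return []
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    res_of = np.asarray(res_of)
    unit = _sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    max_cut = radii.max() * 2 + 2 * contact_pad
    atom_contacts = []
    for ai, aj in tree.query_pairs(max_cut):
        if res_of[ai] == res_of[aj]:
            continue
        cut = radii[ai] + radii[aj] + 2 * contact_pad
        if np.linalg.norm(coords[ai] - coords[aj]) <= cut:
            atom_contacts.append((ai, aj))

    L = len(s.residues)
    rows = [res_of[ai] for ai, _ in atom_contacts]
    cols = [res_of[aj] for _, aj in atom_contacts]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(L, L))
    _, labels = _sparse_components(adj + adj.T, directed=False)

    clusters: dict[int, dict] = {}
    for ai, aj in atom_contacts:
        lab = labels[res_of[ai]]
        c = clusters.setdefault(lab, {"res": set(), "atoms": set(), "area": 0.0})
        c["res"].update((int(res_of[ai]), int(res_of[aj])))
        c["atoms"].update((int(ai), int(aj)))
        c["area"] += _contact_cap_area(coords[ai], radii[ai],
                                       coords[aj], radii[aj],
                                       unit, contact_pad)
    out = [
        HydrophobicCluster(frozenset(c["res"]), len(c["atoms"]), float(c["area"]))
        for c in clusters.values()
        if len(c["res"]) >= min_cluster_size
    ]
    out.sort(key=lambda c: (-c.size, sorted(c.residue_indices)))
    return out


def report(s: Structure, probe: float = DEFAULT_PROBE) -> dict:
    """JSON-serialisable summary of all analyses with default parameters.

    Sub-analyses that fail on a given structure (e.g. contact order on a
    contact-free chain) report an ``error`` string instead of aborting the
    rest.
    """
    out: dict = {"id": s.id, "n_residues": len(s)}
    total, per_res = sasa(s, probe=probe)
    out["sasa_total"] = round(total, 1)
    try:
        out["relative_contact_order"] = round(contact_order(s), 2)
    except ValueError as exc:
        out["relative_contact_order"] = {"error": str(exc)}
    out["n_salt_bridges"] = len(salt_bridges(s))
    out["n_hbonds"] = len(hbonds(s))
    clusters = hydrophobic_clusters(s, min_cluster_size=2)
    out["hydrophobic_clusters"] = [
        {"n_residues": c.size, "area": round(c.area, 1)} for c in clusters
    ]
    return out
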
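"""Coordinate data model, PDB I/O and ideal-geometry fixture generation.

The :class:`Structure` / :class:`Residue` / :class:`Atom` hierarchy is the
universal 3-D object of the package: an ordered list of residues, each an
ordered list of typed heavy atoms.  Residues are addressed everywhere by their
internal sequential index ``0..L-1`` (file order); author numbering
``(chain, resid, icode)`` is preserved for round-tripping only.

PDB reading implements a deliberately narrow single-conformer dialect:
HETATM records and waters are dropped, only blank/'A' altlocs are kept,
and only the first MODEL of a multi-model file is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "build_ideal_ss",
    "make_toy_pair",
    "ToyPair",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

HYDROPHOBIC = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"})
ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"LYS", "ARG", "HIS"})

STANDARD_AA3 = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PDBFormatError(ValueError):
    """Raised when a PDB line cannot be parsed; message names the line number."""


class EmptyStructureError(ValueError):
    """Raised when a file or structure contains no standard residues."""


def residue_classes(name3: str) -> frozenset[str]:
    """Deterministic physicochemical class of a 3-letter residue code."""
    if name3 in HYDROPHOBIC:
        return frozenset({"hydrophobic"})
    if name3 in ACIDIC:
        return frozenset({"acidic"})
    if name3 in BASIC:
        return frozenset({"basic"})
    return frozenset({"polar"})


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class Residue:
    name3: str
    chain: str
    resid: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.name3} {self.chain}{self.resid}{self.icode}: duplicate atom names"
            )

    @property
    def classes(self) -> frozenset[str]:
        return residue_classes(self.name3)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom:
        a = self.atom("CA")
        if a is None:
            raise ValueError(
                f"residue {self.name3} {self.chain}{self.resid}{self.icode} has no CA atom"
            )
        return a

    def translated(self, shift: np.ndarray) -> "Residue":
        shift = np.asarray(shift, dtype=float)
        return replace(
            self,
            atoms=[replace(a, coords=a.coords + shift) for a in self.atoms],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue":
        return replace(
            self,
            atoms=[
                replace(a, coords=rotation @ a.coords + translation)
                for a in self.atoms
            ],
        )


@dataclass
class Structure:
    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")
        keys = [(r.chain, r.resid, r.icode) for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"structure {self.id!r}: duplicate (chain, resid, icode)")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence; non-standard residues map to 'X'."""
        return "".join(THREE_TO_ONE.get(r.name3, "X") for r in self.residues)

    def ca_coords(self, indices: list[int] | None = None) -> np.ndarray:
        """Cα coordinates, (L, 3), optionally restricted to residue indices."""
        residues = self.residues if indices is None else [self.residues[i] for i in indices]
        return np.array([r.ca.coords for r in residues], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return Structure(
            self.id,
            [r.transformed(rotation, translation) for r in self.residues],
        )

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable ATOM record: {exc}") from exc
    if not element:
        # Element column absent in some minimal files: infer from atom name.
        element = name.lstrip("0123456789")[:1]
    return serial, name, altloc, resname, chain, resid, icode, (x, y, z), element


def read_pdb(path, structure_id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    HETATM records and waters are dropped, hydrogens are dropped, only
    blank/'A' altlocs are kept, and records after ``ENDMDL`` (MODEL > 1)
    are ignored.

    Raises :class:`PDBFormatError` naming the offending line number on a
    malformed record and :class:`EmptyStructureError` if no standard
    residues survive.
    """
    path = str(path)
    residues: list[Residue] = []
    current_key = None
    current_atoms: list[Atom] = []
    current_meta = None

    def flush() -> None:
        nonlocal current_atoms, current_meta
        if current_meta is not None and current_atoms:
            resname, chain, resid, icode = current_meta
            residues.append(Residue(resname, chain, resid, icode, current_atoms))
        current_atoms = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "ENDMDL":
                break
            if record != "ATOM  ":
                continue
            serial, name, altloc, resname, chain, resid, icode, xyz, element = (
                _parse_atom_line(line.rstrip("\n"), lineno)
            )
            if resname in WATER_NAMES or resname not in STANDARD_AA3:
                continue
            if altloc not in (" ", "A"):
                continue
            if element == "H" or name.startswith("H") or (name[:1].isdigit() and "H" in name):
                continue
            key = (chain, resid, icode)
            if key != current_key:
                flush()
                current_key = key
                current_meta = (resname, chain, resid, icode)
            current_atoms.append(Atom(serial, name, element, np.array(xyz)))
    flush()

    if not residues:
        raise EmptyStructureError(f"{path}: no standard protein residues found")
    sid = structure_id or path.rsplit("/", 1)[-1].removesuffix(".pdb")
    return Structure(sid, residues)


def write_pdb(s: Structure, path, bfactors: list[float] | None = None) -> None:
    """Write ``s`` in fixed-column PDB format with serials renumbered from 1.

    ``bfactors`` is an optional per-residue list written into the B-factor
    column (used by the builder to record parent provenance).
    """
    if not s.residues:
        raise EmptyStructureError("refusing to write a structure with no residues")
    if bfactors is not None and len(bfactors) != len(s.residues):
        raise ValueError("bfactors must have one entry per residue")
    serial = 0
    lines = []
    for i, res in enumerate(s.residues):
        b = bfactors[i] if bfactors is not None else 0.0
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:>5} {atom.name:<4.4}{'':1}{res.name3:<3} "
                f"{res.chain or 'A':1}{res.resid:>4}{res.icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
                f"{atom.element:>2}"
            )
    lines.append("END")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ideal-geometry builder (NeRF internal-coordinate chain growth)

# Engh–Huber style backbone internal coordinates (Å, degrees).
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_C_CA_CB = 110.1
_OMEGA = 180.0

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "loop": (-60.0, 150.0),  # PPII-like; keeps helix/strand transitions open
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_ss(spec: list[tuple[str, int]], structure_id: str = "ideal") -> Structure:
    """Build a backbone + Cβ poly-Ala chain from ideal internal geometry.

    ``spec`` is a list of ``(kind, length)`` blocks with kind one of
    ``helix`` (φ/ψ = −57°/−47°), ``strand`` (−139°/+135°) or ``loop``.
    Deterministic; standard bond lengths and angles throughout.
    """
    phi_psi: list[tuple[float, float]] = []
    for kind, length in spec:
        if kind not in _PHI_PSI:
            raise ValueError(f"unknown secondary-structure kind {kind!r}")
        if length < 1:
            raise ValueError(f"block ({kind}, {length}): length must be >= 1")
        phi_psi.extend([_PHI_PSI[kind]] * length)
    n_res = len(phi_psi)

    # Seed the first residue in the xy-plane.
    n_xyz = [np.zeros(3)]
    ca_xyz = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    c_xyz = [ca_xyz[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]

    for i in range(1, n_res):
        _, psi_prev = phi_psi[i - 1]
        phi_i, _ = phi_psi[i]
        n_xyz.append(_nerf(n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
                           _B_C_N, _A_CA_C_N, psi_prev))
        ca_xyz.append(_nerf(ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
                            _B_N_CA, _A_C_N_CA, _OMEGA))
        c_xyz.append(_nerf(c_xyz[i - 1], n_xyz[i], ca_xyz[i],
                           _B_CA_C, _A_N_CA_C, phi_i))

    residues = []
    for i in range(n_res):
        if i < n_res - 1:
            o = _nerf(n_xyz[i + 1], ca_xyz[i], c_xyz[i], _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = _nerf(n_xyz[i], ca_xyz[i], c_xyz[i], _B_C_O, _A_CA_C_O,
                      phi_psi[i][1] + 180.0)
        cb = _nerf(n_xyz[i], c_xyz[i], ca_xyz[i], _B_CA_CB, _A_C_CA_CB, -122.6)
        atoms = [
            Atom(1, "N", "N", n_xyz[i]),
            Atom(2, "CA", "C", ca_xyz[i]),
            Atom(3, "C", "C", c_xyz[i]),
            Atom(4, "O", "O", o),
            Atom(5, "CB", "C", cb),
        ]
        residues.append(Residue("ALA", "A", i + 1, "", atoms))
    return Structure(structure_id, residues)


# ---------------------------------------------------------------------------
# Toy parent-pair generator


@dataclass
class ToyPair:
    """A synthetic parent pair with a known shared fragment.

    ``fusable_columns`` are the alignment columns engineered to superpose
    below 1.0 Å (Cα–Cα, after a global least-squares fit); all other aligned
    columns are engineered to lie above it.
    """

    query: Structure
    subject: Structure
    hit: "object"  # chimeraforge.hits.Hit; forward ref avoids import cycle
    fusable_columns: list[int]


_Q_NFLANK, _Q_CFLANK = 4, 4
_S_NFLANK, _S_CFLANK = 3, 5


def make_toy_pair(n_shared: int, n_fusable: int, seed: int,
                  detailed: bool = False):
    """Build two ideal-geometry parents sharing an ``n_shared``-residue fragment.

    Exactly ``n_fusable`` aligned Cα pairs lie below the 1.0 Å fusion cutoff
    after global superposition (engineered with safety margins: fusable pairs
    < 0.8 Å, the rest > 1.3 Å), so a downstream fusion-point scan at the
    default cutoff recovers exactly the engineered columns.  Returns
    ``(query, subject, hit)``, or a :class:`ToyPair` when ``detailed=True``.
    """
    from .hits import Hit  # deferred: hits does not import structures
    from .superpose import kabsch, tm_score

    if not 0 <= n_fusable <= n_shared:
        raise ValueError(f"n_fusable must be in [0, n_shared]; got {n_fusable} > {n_shared}")
    if n_shared < 3:
        raise ValueError("n_shared must be >= 3 for a superposable fragment")

    rng = np.random.default_rng(seed)
    total = _Q_NFLANK + n_shared + _S_CFLANK + 1
    chain = build_ideal_ss([("strand", total)], structure_id="toy_chain")

    q_res = [replace(r) for r in chain.residues[: _Q_NFLANK + n_shared + _Q_CFLANK]]
    s_res = [replace(r) for r in
             chain.residues[_Q_NFLANK - _S_NFLANK: _Q_NFLANK + n_shared + _S_CFLANK]]
    q_start, q_end = _Q_NFLANK, _Q_NFLANK + n_shared
    s_start, s_end = _S_NFLANK, _S_NFLANK + n_shared

    fusable = sorted(rng.choice(n_shared, size=n_fusable, replace=False).tolist())
    fusable_set = set(fusable)
    nonfusable = [i for i in range(n_shared) if i not in fusable_set]

    # Displace non-fusable subject residues off the shared backbone,
    # alternating above/below the chain plane so the net shift (which the
    # superposition would absorb) stays near zero.
    disp = {i: np.array([0.0, 0.0, 3.0 if k % 2 == 0 else -3.0])
            for k, i in enumerate(nonfusable)}
    base_frag = [s_res[s_start + i].atoms for i in range(n_shared)]

    def set_fragment(offsets: dict[int, np.ndarray]) -> None:
        for i in range(n_shared):
            shift = offsets.get(i, np.zeros(3))
            s_res[s_start + i] = replace(
                s_res[s_start + i],
                atoms=[replace(a, coords=a.coords + shift) for a in base_frag[i]],
            )

    q_frag_ca = np.array([q_res[q_start + i].atom("CA").coords for i in range(n_shared)])
    offsets = dict(disp)
    set_fragment(offsets)
    for _ in range(100):
        s_frag_ca = np.array([s_res[s_start + i].atom("CA").coords
                              for i in range(n_shared)])
        sup = kabsch(q_frag_ca, s_frag_ca)
        d = sup.pair_distances
        ok_fus = all(d[i] < 0.8 for i in fusable)
        ok_non = all(d[i] > 1.3 for i in nonfusable)
        if ok_fus and ok_non:
            break
        for i in fusable:
            # Snap the residue so its Cα maps exactly onto the query Cα.
            target = sup.rotation.T @ (q_frag_ca[i] - sup.translation)
            offsets[i] = offsets.get(i, np.zeros(3)) + (target - s_frag_ca[i])
        for i in nonfusable:
            if d[i] <= 1.3:
                offsets[i] = offsets[i] + 0.7 * disp[i] / np.linalg.norm(disp[i])
        set_fragment(offsets)
    else:  # pragma: no cover - construction loop converges in a few steps
        raise RuntimeError("toy-pair construction did not converge")

    # Hide the construction frame behind a random rigid motion of the subject.
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0.2, 2.8)
    kmat = np.array([[0, -axis[2], axis[1]],
                     [axis[2], 0, -axis[0]],
                     [-axis[1], axis[0], 0]])
    rot = np.eye(3) + math.sin(theta) * kmat + (1 - math.cos(theta)) * (kmat @ kmat)
    trans = rng.uniform(-20, 20, size=3)
    s_res = [r.transformed(rot, trans) for r in s_res]

    for i, r in enumerate(q_res):
        q_res[i] = replace(r, chain="A", resid=i + 1)
    for i, r in enumerate(s_res):
        s_res[i] = replace(r, chain="A", resid=i + 1)
    query = Structure("dtoyqa_", q_res)
    subject = Structure("dtoysa_", s_res)

    final_sup = kabsch(
        query.ca_coords(list(range(q_start, q_end))),
        subject.ca_coords(list(range(s_start, s_end))),
    )
    hit = Hit(
        query_id="dtoyqa_", subject_id="dtoysa_",
        q_cluster=1, s_cluster=2,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        q_aln="A" * n_shared, s_aln="A" * n_shared,
        probability=85.0,
        rmsd=round(float(final_sup.rmsd), 3),
        tm_score=round(float(tm_score(final_sup.pair_distances, len(query))), 3),
        identity=100.0,
        q_scop="c.37.1.10", s_scop="c.2.1.5",
    )
    pair = ToyPair(query, subject, hit, fusable)
    return pair if detailed else (query, subject, hit)
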
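"""Single-crossover chimera construction.

Pipeline: map the hit's profile-HMM alignment onto the two parent structures
(one Cα pair per gap-free alignment column), superpose the fragment Cα sets
(globally or per gap-delimited segment), call every aligned column whose
post-superposition Cα–Cα distance falls below a cutoff (default 1 Å) a
*fusion point*, and assemble two chimeras per fusion point: combination 1
takes its N-terminus from the query parent, combination 2 from the subject.
Candidates whose two parent halves collide backbone-on-backbone are rejected.

Each fusion point can thus yield at most two chimeras, so an alignment with
``n`` mapped positions bounds the candidate count at ``2n`` before distance
and clash filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .hits import Hit
from .structures import Residue, Structure
from .superpose import Superposition, partition_segments, superpose_fragment

__all__ = [
    "AlignmentMap",
    "FusionPoint",
    "Chimera",
    "BuildReport",
    "MappingError",
    "map_alignment",
    "find_fusion_points",
    "theoretical_max_chimeras",
    "assemble",
    "clash_check",
    "build_all",
    "build_report",
]

DEFAULT_FUSION_CUTOFF = 1.0  # Å, Cα–Cα after superposition
DEFAULT_CLASH_DIST = 2.5  # Å, backbone heavy atoms across the junction


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentMap:
    """Per-column pairing of query/subject residue indices.

    ``pairs`` holds ``(alignment_column, q_res_index, s_res_index)`` for each
    gap-free alignment column; residue indices are internal sequential
    (0-based) and strictly increasing.
    """

    pairs: tuple[tuple[int, int, int], ...]
    q_struct: Structure
    s_struct: Structure
    partition: object  # SegmentPartition

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FusionPoint:
    alignment_column: int
    q_res_index: int
    s_res_index: int
    ca_distance: float  # Å, post-superposition
    superposition: Superposition  # governing transform (subject -> query frame)


@dataclass
class Chimera:
    """An assembled single-crossover structure with per-residue provenance."""

    name: str
    combination: int  # 1 = query N-terminus, 2 = subject N-terminus
    fusion: FusionPoint
    structure: Structure
    provenance: list[str]  # "query" | "subject" per residue

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.structure):
            raise ValueError("provenance must cover every residue")


def map_alignment(hit: Hit, q: Structure, s: Structure,
                  min_seq_identity: float = 0.9) -> AlignmentMap:
    """Map the hit's alignment columns onto residue indices of both parents.

    Columns with a gap on either side are excluded.  The alignment letters
    are checked against the structure sequences over the fragment; a match
    fraction below ``min_seq_identity`` (per side, 'X' structure residues
    ignored) aborts with column diagnostics.
    """
    for label, struct, start, end in (
        ("query", q, hit.q_start, hit.q_end),
        ("subject", s, hit.s_start, hit.s_end),
    ):
        if not (0 <= start <= end <= len(struct)):
            raise MappingError(
                f"{label} fragment bounds [{start}, {end}) overflow structure "
                f"{struct.id} of length {len(struct)}"
            )

    pairs: list[tuple[int, int, int]] = []
    mismatches: list[str] = []
    checked = matched = 0
    qi, si = hit.q_start, hit.s_start
    for col, (qc, sc) in enumerate(zip(hit.q_aln, hit.s_aln)):
        if qc != "-" and sc != "-":
            pairs.append((col, qi, si))
        for letter, struct, idx in ((qc, q, qi), (sc, s, si)):
            if letter == "-":
                continue
            actual = struct.sequence[idx]
            if actual != "X":
                checked += 1
                if letter.upper() == actual:
                    matched += 1
                else:
                    mismatches.append(
                        f"column {col}: {struct.id}[{idx}] is {actual}, "
                        f"alignment says {letter}"
                    )
        if qc != "-":
            qi += 1
        if sc != "-":
            si += 1

    if checked and matched / checked < min_seq_identity:
        detail = "; ".join(mismatches[:5])
        raise MappingError(
            f"alignment/structure sequence agreement {matched}/{checked} below "
            f"{min_seq_identity:.0%}: {detail}"
        )
    for _, q_idx, s_idx in pairs:
        q.residues[q_idx].ca
        s.residues[s_idx].ca

    return AlignmentMap(
        pairs=tuple(pairs),
        q_struct=q,
        s_struct=s,
        partition=partition_segments(hit.q_aln, hit.s_aln),
    )


def find_fusion_points(amap: AlignmentMap, mode: str = "global",
                       cutoff: float = DEFAULT_FUSION_CUTOFF,
                       min_seg_len: int = 3) -> list[FusionPoint]:
    """Aligned columns whose superposed Cα pairs lie strictly below
    ``cutoff`` Å, in sequence order.

    In partial mode every column's distance is measured under its own
    segment's transform; columns in segments shorter than ``min_seg_len``
    are not fusion-point candidates.
    """
    fits = superpose_fragment(amap, mode=mode, min_seg_len=min_seg_len)
    cols = np.array([p[0] for p in amap.pairs])
    out: list[FusionPoint] = []
    for (start, end), sup in fits:
        mask = (cols >= start) & (cols < end)
        q_ca = amap.q_struct.ca_coords([p[1] for p, m in zip(amap.pairs, mask) if m])
        s_ca = amap.s_struct.ca_coords([p[2] for p, m in zip(amap.pairs, mask) if m])
        dists = np.linalg.norm(sup.apply(s_ca) - q_ca, axis=1)
        for (col, qi, si), d in zip(
            (p for p, m in zip(amap.pairs, mask) if m), dists
        ):
            if d < cutoff:
                out.append(FusionPoint(col, qi, si, float(d), sup))
    out.sort(key=lambda fp: fp.alignment_column)
    return out


def theoretical_max_chimeras(amap: AlignmentMap) -> int:
    """Upper bound on candidate chimeras: two combinations per mapped
    alignment position, before distance and clash filtering."""
    return 2 * len(amap.pairs)


def assemble(amap: AlignmentMap, fp: FusionPoint, combination: int) -> Chimera:
    """Assemble one chimera at a fusion point.

    Combination 1 keeps the query residues up to and including the fusion
    column's query residue, followed by the subject residues after its
    subject residue, with all subject coordinates brought into the query
    frame by the governing superposition.  Combination 2 is the symmetric
    subject-N-terminal construct.  Output is renumbered 1..L on chain 'A'.
    """
    if combination not in (1, 2):
        raise ValueError(f"combination must be 1 or 2, got {combination}")
    sup = fp.superposition
    s_moved = [r.transformed(sup.rotation, sup.translation)
               for r in amap.s_struct.residues]
    q_res = amap.q_struct.residues

    if combination == 1:
        head = q_res[: fp.q_res_index + 1]
        tail = s_moved[fp.s_res_index + 1:]
        provenance = ["query"] * len(head) + ["subject"] * len(tail)
    else:
        head = s_moved[: fp.s_res_index + 1]
        tail = q_res[fp.q_res_index + 1:]
        provenance = ["subject"] * len(head) + ["query"] * len(tail)
    if not head or not tail:
        raise ValueError(
            f"fusion at column {fp.alignment_column} leaves an empty "
            f"{'tail' if not tail else 'head'}; degenerate chimera"
        )

    residues = [
        replace(r, chain="A", resid=i + 1, icode="")
        for i, r in enumerate(head + tail)
    ]
    name = f"comb{combination}_{fp.alignment_column}"
    return Chimera(name, combination, fp,
                   Structure(name, residues), provenance)


def clash_check(ch: Chimera, d_clash: float = DEFAULT_CLASH_DIST) -> bool:
    """True if any backbone heavy-atom pair (N, CA, C, O) between a
    query-derived and a subject-derived residue lies closer than ``d_clash``.

    Atom pairs between residues adjacent in the chimera sequence (in
    practice: the junction pair, whose peptide linkage necessarily places
    backbone atoms within bonding distance) are excluded.  Intra-parent
    geometry is not checked — the parents are experimental structures.
    """
    coords, res_idx, tags = [], [], []
    for i, (res, tag) in enumerate(zip(ch.structure.residues, ch.provenance)):
        for a in res.atoms:
            if a.is_backbone:
                coords.append(a.coords)
                res_idx.append(i)
                tags.append(tag)
    coords = np.asarray(coords)
    tree = cKDTree(coords)
    for ai, aj in tree.query_pairs(d_clash):
        if tags[ai] == tags[aj]:
            continue
        if abs(res_idx[ai] - res_idx[aj]) <= 1:
            continue
        return True
    return False


def build_all(hit: Hit, q: Structure, s: Structure, mode: str = "global",
              cutoff: float = DEFAULT_FUSION_CUTOFF,
              clash_dist: float = DEFAULT_CLASH_DIST,
              min_seg_len: int = 3) -> list[Chimera]:
    """All clash-free chimeras for a hit: both combinations at every fusion
    point, with degenerate and clashing candidates dropped."""
    return build_report(hit, q, s, mode=mode, cutoff=cutoff,
                        clash_dist=clash_dist, min_seg_len=min_seg_len).chimeras


@dataclass
class BuildReport:
    """Counts at each stage of the pipeline, plus the surviving chimeras."""

    n_mapped_positions: int
    max_candidates: int  # 2 per mapped position
    n_fusion_points: int
    n_candidates: int  # entering the clash filter (2 per fusion point, minus degenerate)
    n_degenerate: int
    n_clashing: int
    chimeras: list[Chimera]


def build_report(hit: Hit, q: Structure, s: Structure, mode: str = "global",
                 cutoff: float = DEFAULT_FUSION_CUTOFF,
                 clash_dist: float = DEFAULT_CLASH_DIST,
                 min_seg_len: int = 3) -> BuildReport:
    amap = map_alignment(hit, q, s)
    fusion_points = find_fusion_points(amap, mode=mode, cutoff=cutoff,
                                       min_seg_len=min_seg_len)
    candidates: list[Chimera] = []
    n_degenerate = 0
    for fp in fusion_points:
        for combination in (1, 2):
            try:
                candidates.append(assemble(amap, fp, combination))
            except ValueError:
                n_degenerate += 1
    kept = [ch for ch in candidates if not clash_check(ch, clash_dist)]
    return BuildReport(
        n_mapped_positions=len(amap),
        max_candidates=theoretical_max_chimeras(amap),
        n_fusion_points=len(fusion_points),
        n_candidates=len(candidates),
        n_degenerate=n_degenerate,
        n_clashing=len(candidates) - len(kept),
        chimeras=kept,
    )


def write_chimera_pdb(ch: Chimera, path) -> None:
    """Write a chimera with parent provenance in the B-factor column
    (query = 1.0, subject = 2.0)."""
    from .structures import write_pdb

    bfac = [1.0 if tag == "query" else 2.0 for tag in ch.provenance]
    write_pdb(ch.structure, path, bfactors=bfac)
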
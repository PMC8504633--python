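"""Rigid-body fragment superposition, RMSD and TM-score.

The builder's alignment-guided superposition comes in two flavours: a single
global least-squares fit over every aligned Cα pair, or a *partial* mode that
fits each gap-delimited alignment segment independently (useful when a long
fragment is internally hinged, e.g. a run of βα-motifs whose relative
orientation differs between the parents).  Both reduce to the Kabsch
algorithm: the closed-form SVD solution of the orthogonal Procrustes problem
with reflection correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Superposition",
    "SegmentPartition",
    "kabsch",
    "partition_segments",
    "superpose_fragment",
    "tm_score",
]


@dataclass(frozen=True)
class Superposition:
    """An optimal rigid map ``x -> rotation @ x + translation`` of the mobile
    coordinate set onto the reference, with the per-pair Cα distances it
    induces.  ``rmsd**2 == mean(pair_distances**2)`` over the fitted pairs."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    pair_distances: np.ndarray  # (N,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SegmentPartition:
    """Gap-delimited alignment-column ranges, half-open and ascending."""

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if start >= end:
                raise ValueError(f"empty segment [{start}, {end})")
            if start <= prev_end:
                raise ValueError("segments must be non-overlapping and ascending")
            prev_end = end - 1

    def __len__(self) -> int:
        return len(self.segments)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``coords_b`` onto
    ``coords_a`` (positional correspondence, N >= 3), reflection-corrected.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")

    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    ac = a - cen_a
    bc = b - cen_b

    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] - s[2] < 1e-12 * max(s[0], 1.0) and s[2] < 1e-9 * max(s[0], 1.0):
        warnings.warn("degenerate (near-collinear) point set; rotation may be "
                      "under-determined", stacklevel=2)
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cen_a - rotation @ cen_b

    moved = b @ rotation.T + translation
    dists = np.linalg.norm(moved - a, axis=1)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return Superposition(rotation, translation, rmsd, dists)


def partition_segments(q_aln: str, s_aln: str) -> SegmentPartition:
    """Split an alignment into maximal runs of columns where neither string
    has a gap.  Gap columns are the segment boundaries."""
    if len(q_aln) != len(s_aln):
        raise ValueError("alignment strings must have equal length")
    segments: list[tuple[int, int]] = []
    start = None
    for col, (qc, sc) in enumerate(zip(q_aln, s_aln)):
        aligned = qc != "-" and sc != "-"
        if aligned and start is None:
            start = col
        elif not aligned and start is not None:
            segments.append((start, col))
            start = None
    if start is not None:
        segments.append((start, len(q_aln)))
    if not segments:
        raise ValueError("alignment has no gap-free columns; nothing to partition")
    return SegmentPartition(tuple(segments))


def superpose_fragment(amap, mode: str = "global", min_seg_len: int = 3
                       ) -> list[tuple[tuple[int, int], Superposition]]:
    """Superpose aligned fragment Cα atoms of an :class:`AlignmentMap`.

    ``global`` returns one fit over every aligned pair; ``partial`` fits each
    gap-delimited segment with at least ``min_seg_len`` aligned columns
    independently (shorter segments are excluded — 1–2-point fits are
    ill-conditioned and their columns are dropped from fusion-point
    candidacy).  Returns ``(column_range, Superposition)`` tuples.
    """
    pairs = amap.pairs
    if len(pairs) < 3:
        raise ValueError("need at least 3 aligned pairs to superpose")
    q_ca = amap.q_struct.ca_coords([p[1] for p in pairs])
    s_ca = amap.s_struct.ca_coords([p[2] for p in pairs])
    cols = np.array([p[0] for p in pairs])

    if mode == "global":
        span = (int(cols[0]), int(cols[-1]) + 1)
        return [(span, kabsch(q_ca, s_ca))]
    if mode != "partial":
        raise ValueError(f"unknown mode {mode!r}; expected 'global' or 'partial'")

    out = []
    for start, end in amap.partition.segments:
        mask = (cols >= start) & (cols < end)
        if int(mask.sum()) < max(min_seg_len, 3):
            continue
        out.append(((start, end), kabsch(q_ca[mask], s_ca[mask])))
    if not out:
        raise ValueError(
            f"no alignment segment has >= {min_seg_len} aligned columns; "
            "use mode='global' instead"
        )
    return out


def tm_score(pair_distances, l_target: int) -> float:
    """Template-modelling score of an alignment against a target of length
    ``l_target``: ``(1/L) * sum(1 / (1 + (d_i/d0)^2))`` with the standard
    length-dependent scale ``d0 = 1.24 (L - 15)^(1/3) - 1.8``, floored at
    0.5 Å for very short targets."""
    d = np.asarray(pair_distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("pair distances must be non-negative")
    if l_target <= 15:
        warnings.warn(f"L_target={l_target} <= 15: using d0 floor of 0.5 Å",
                      stacklevel=2)
        d0 = 0.5
    else:
        d0 = max(1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)
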
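"""Fragment-homology hit records: schema, TSV/SQLite loading and filtering.

A *hit* links two SCOPe-style protein domains that share an evolutionarily
conserved sub-domain fragment, carrying the profile-HMM (HHsearch) alignment
of the fragment, its bounds on each domain, and similarity scores.  A small
built-in toy table (``chimeraforge/data/toy_hits.tsv``) stands in for a full
fragment database and exercises the same query semantics: score filtering,
SCOPe-lineage group fetches and per-domain exclusion.

Fragment bounds are 0-based half-open indices on the internal sequential
residue index of each domain (file order), not author numbering.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

__all__ = [
    "Hit",
    "FilterCriteria",
    "HitValidationError",
    "load_hits",
    "load_toy_hits",
    "filter_hits",
    "fetch_group",
    "exclude_domain",
]

_COLUMNS = [
    "query_id", "q_cluster", "subject_id", "s_cluster",
    "q_start", "q_end", "s_start", "s_end",
    "q_aln", "s_aln",
    "probability", "rmsd", "tm_score", "identity",
    "q_scop", "s_scop",
]

_INT_COLS = {"q_cluster", "s_cluster", "q_start", "q_end", "s_start", "s_end"}
_FLOAT_COLS = {"probability", "rmsd", "tm_score", "identity"}


class HitValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Hit:
    """One fragment-homology record between a query and a subject domain."""

    query_id: str
    subject_id: str
    q_cluster: int
    s_cluster: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_aln: str
    s_aln: str
    probability: float  # HHsearch probability, percent
    rmsd: float  # Å, over the fragment alignment
    tm_score: float
    identity: float  # percent
    q_scop: str  # dotted lineage, class.fold.superfamily.family
    s_scop: str

    def __post_init__(self) -> None:
        pair = f"{self.query_id}/{self.subject_id}"
        if len(self.q_aln) != len(self.s_aln):
            raise HitValidationError(
                f"hit {pair}: alignment strings differ in length "
                f"({len(self.q_aln)} vs {len(self.s_aln)})"
            )
        q_ungapped = len(self.q_aln) - self.q_aln.count("-")
        s_ungapped = len(self.s_aln) - self.s_aln.count("-")
        if q_ungapped != self.q_end - self.q_start:
            raise HitValidationError(
                f"hit {pair}: q_aln has {q_ungapped} residues but bounds span "
                f"{self.q_end - self.q_start}"
            )
        if s_ungapped != self.s_end - self.s_start:
            raise HitValidationError(
                f"hit {pair}: s_aln has {s_ungapped} residues but bounds span "
                f"{self.s_end - self.s_start}"
            )
        if not 0.0 <= self.probability <= 100.0:
            raise HitValidationError(f"hit {pair}: probability outside [0, 100]")
        if self.rmsd < 0:
            raise HitValidationError(f"hit {pair}: negative RMSD")

    @property
    def length(self) -> int:
        """Fragment length, measured on the query side."""
        return self.q_end - self.q_start

    def node_id(self, side: str) -> str:
        """Network node identity: domain id + fragment-cluster tag."""
        if side == "query":
            return f"{self.query_id}_{self.q_cluster}"
        if side == "subject":
            return f"{self.subject_id}_{self.s_cluster}"
        raise ValueError(f"side must be 'query' or 'subject', got {side!r}")


@dataclass(frozen=True)
class FilterCriteria:
    """Score thresholds for hit selection.  Probability and TM-score bounds
    are strict inequalities, length bounds inclusive; any criterion can be
    disabled by setting it to None."""

    min_probability: float | None = 70.0
    max_rmsd: float | None = 3.0
    min_len: int | None = 10
    max_len: int | None = 200
    max_tm: float | None = 0.3

    def __post_init__(self) -> None:
        if (self.min_len is not None and self.max_len is not None
                and self.min_len > self.max_len):
            raise ValueError("min_len must be <= max_len")

    def accepts(self, hit: Hit) -> bool:
        if self.min_probability is not None and not hit.probability > self.min_probability:
            return False
        if self.max_rmsd is not None and not hit.rmsd < self.max_rmsd:
            return False
        length = hit.length
        if self.min_len is not None and length < self.min_len:
            return False
        if self.max_len is not None and length > self.max_len:
            return False
        if self.max_tm is not None and not hit.tm_score < self.max_tm:
            return False
        return True


def _hits_from_frame(df: pd.DataFrame, source: str) -> list[Hit]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise HitValidationError(f"{source}: missing columns {missing}")
    hits = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {}
        for f in fields(Hit):
            value = getattr(row, f.name)
            if f.name in _INT_COLS:
                value = int(value)
            elif f.name in _FLOAT_COLS:
                value = float(value)
            else:
                value = str(value)
            kwargs[f.name] = value
        try:
            hits.append(Hit(**kwargs))
        except HitValidationError as exc:
            raise HitValidationError(f"{source}, row {row_no}: {exc}") from exc
    return hits


def load_hits(path, format: str = "tsv") -> list[Hit]:
    """Load and validate a hit table from a TSV file (with header) or a
    single-table SQLite database (table ``hits``, same columns)."""
    path = str(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
    elif format == "sqlite":
        with sqlite3.connect(path) as conn:
            df = pd.read_sql_query("SELECT * FROM hits", conn)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'sqlite'")
    return _hits_from_frame(df, path)


def load_toy_hits() -> list[Hit]:
    """The packaged 12-row toy hit table."""
    ref = resources.files("chimeraforge").joinpath("data/toy_hits.tsv")
    with resources.as_file(ref) as path:
        return load_hits(path, format="tsv")


def filter_hits(hits: list[Hit], criteria: FilterCriteria | None = None) -> list[Hit]:
    """Order-preserving subset of hits passing every enabled criterion."""
    criteria = criteria or FilterCriteria()
    return [h for h in hits if criteria.accepts(h)]


def _lineage_matches(lineage: str, prefix_fields: list[str]) -> bool:
    parts = lineage.split(".")
    if len(parts) < len(prefix_fields):
        return False
    return parts[: len(prefix_fields)] == prefix_fields


def fetch_group(hits: list[Hit], scop_query: str, side: str = "either") -> list[Hit]:
    """Hits whose SCOPe lineage starts with ``scop_query`` on whole-field
    boundaries ("c.2" matches "c.2.1.2" but not "c.21.1.1").

    ``side`` selects which lineage must match: ``query``, ``subject``,
    ``either`` or ``both``.
    """
    prefix_fields = scop_query.split(".")
    if not 1 <= len(prefix_fields) <= 4 or any(not f for f in prefix_fields):
        raise ValueError(f"malformed SCOPe prefix {scop_query!r}")
    if side not in ("query", "subject", "either", "both"):
        raise ValueError(f"side must be query|subject|either|both, got {side!r}")

    out = []
    for h in hits:
        q = _lineage_matches(h.q_scop, prefix_fields)
        s = _lineage_matches(h.s_scop, prefix_fields)
        keep = {"query": q, "subject": s, "either": q or s, "both": q and s}[side]
        if keep:
            out.append(h)
    return out


def exclude_domain(hits: list[Hit], domain_id: str) -> list[Hit]:
    """Drop every hit touching ``domain_id`` on either side, regardless of
    its fragment-cluster tag (e.g. removing a misclassified domain that
    appears as both ``<id>_2`` and ``<id>_13``)."""
    return [h for h in hits
            if h.query_id != domain_id and h.subject_id != domain_id]
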
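"""Reading homology-search tabular output and reducing hits to species sets.

The expected input is BLAST/PSI-BLAST ``-outfmt 6``-style tab-separated
output with a configurable column order; the recommended column set is
``qseqid sseqid evalue qlen slen staxids``. When the search output lacks a
taxid column, a two-column accession-to-taxid mapping file can be joined in
afterwards with :func:`attach_taxids`.

Hit filtering follows the profile-construction protocol: E-value at most
0.001, and the subject sequence length within 80%-120% of the query sequence
length (both boundaries inclusive — a subject at exactly 80% or 120% is
kept). Lengths are full sequence lengths, not alignment lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from .taxonomy import TaxonomyDB

__all__ = [
    "BlastHit",
    "HitFilterPolicy",
    "BlastParseError",
    "DEFAULT_COLUMNS",
    "parse_blast_tab",
    "load_taxid_map",
    "attach_taxids",
    "filter_hits",
    "hits_to_species_sets",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = ("qseqid", "sseqid", "evalue", "qlen", "slen", "staxids")

# standard outfmt-6 fields we accept but do not use
_IGNORED_COLUMNS = frozenset(
    {"pident", "length", "mismatch", "gapopen", "qstart", "qend",
     "sstart", "send", "bitscore", "sscinames", "stitle"}
)
_KNOWN_COLUMNS = frozenset(DEFAULT_COLUMNS) | _IGNORED_COLUMNS


class BlastParseError(ValueError):
    pass


@dataclass(frozen=True)
class BlastHit:
    """One query-subject hit with the quantities the filters act on.

    ``subject_taxids`` may be empty until a mapping file is joined; RefSeq
    identical-sequence merges can carry several taxids per subject, all of
    which contribute to the species set.
    """

    query_id: str
    subject_id: str
    evalue: float
    query_length: Optional[int] = None
    subject_length: Optional[int] = None
    subject_taxids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")
        for ln in (self.query_length, self.subject_length):
            if ln is not None and ln < 1:
                raise ValueError(f"non-positive sequence length {ln}")
        if len(set(self.subject_taxids)) != len(self.subject_taxids):
            raise ValueError("duplicate subject taxids")


@dataclass(frozen=True)
class HitFilterPolicy:
    """Thresholds for accepting a hit into a profile.

    ``exclude_taxids`` removes hits to the query organism itself (e.g. 9606
    for a human proteome) so a profile records non-self homology only.
    """

    evalue_max: float = 0.001
    min_len_frac: float = 0.8
    max_len_frac: float = 1.2
    exclude_taxids: frozenset[int] = frozenset()

    def __post_init__(self):
        if not (0 < self.min_len_frac <= 1 <= self.max_len_frac):
            raise ValueError(
                f"need 0 < min_len_frac <= 1 <= max_len_frac, "
                f"got {self.min_len_frac}, {self.max_len_frac}"
            )


def parse_blast_tab(
    stream: Iterable[str],
    column_spec: tuple[str, ...] = DEFAULT_COLUMNS,
) -> list[BlastHit]:
    """Parse tab-separated hits, one per row; all rows for a query-subject
    pair are retained (deduplication happens at profile construction).

    Raises :class:`BlastParseError` naming the line for malformed rows, and
    for column names outside the known outfmt-6 vocabulary.
    """
    unknown = set(column_spec) - _KNOWN_COLUMNS
    if unknown:
        raise BlastParseError(f"unknown column name(s): {sorted(unknown)}")
    for required in ("qseqid", "sseqid", "evalue"):
        if required not in column_spec:
            raise BlastParseError(f"column_spec must include {required!r}")
    col = {name: i for i, name in enumerate(column_spec)}
    hits = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(column_spec):
            raise BlastParseError(
                f"line {lineno}: expected {len(column_spec)} fields, got {len(fields)}"
            )
        try:
            taxids: tuple[int, ...] = ()
            if "staxids" in col:
                raw = fields[col["staxids"]]
                if raw and raw not in ("N/A", "-"):
                    taxids = tuple(dict.fromkeys(int(t) for t in raw.split(";")))
            hits.append(
                BlastHit(
                    query_id=fields[col["qseqid"]],
                    subject_id=fields[col["sseqid"]],
                    evalue=float(fields[col["evalue"]]),
                    query_length=int(fields[col["qlen"]]) if "qlen" in col else None,
                    subject_length=int(fields[col["slen"]]) if "slen" in col else None,
                    subject_taxids=taxids,
                )
            )
        except ValueError as exc:
            raise BlastParseError(f"line {lineno}: {exc}") from exc
    return hits


def load_taxid_map(stream: Iterable[str]) -> dict[str, tuple[int, ...]]:
    """Two-column (accession TAB taxid) mapping; repeated accessions accumulate."""
    mapping: dict[str, tuple[int, ...]] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise BlastParseError(f"mapping line {lineno}: expected 2 fields")
        try:
            taxid = int(fields[1])
        except ValueError as exc:
            raise BlastParseError(f"mapping line {lineno}: {exc}") from exc
        prev = mapping.get(fields[0], ())
        if taxid not in prev:
            mapping[fields[0]] = prev + (taxid,)
    return mapping


def attach_taxids(
    hits: Iterable[BlastHit], mapping: Mapping[str, tuple[int, ...]]
) -> list[BlastHit]:
    """Fill ``subject_taxids`` from an accession-to-taxid mapping; hits whose
    subject is absent from the mapping keep their existing (possibly empty)
    taxid tuple."""
    out = []
    for h in hits:
        if not h.subject_taxids and h.subject_id in mapping:
            h = replace(h, subject_taxids=mapping[h.subject_id])
        out.append(h)
    return out


def filter_hits(hits: Iterable[BlastHit], policy: HitFilterPolicy) -> list[BlastHit]:
    """Keep hits passing the E-value and length-fraction thresholds.

    Boundaries are inclusive; comparisons use the subject/query length ratio
    so that an exactly-80% or exactly-120% subject is retained. Hits whose
    raw subject taxids intersect ``policy.exclude_taxids`` are removed.
    Idempotent, order-preserving.
    """
    kept = []
    for h in hits:
        if h.query_length is None or h.subject_length is None:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} lacks query/subject length"
            )
        if h.evalue > policy.evalue_max:
            continue
        ratio = h.subject_length / h.query_length
        if not (policy.min_len_frac <= ratio <= policy.max_len_frac):
            continue
        if policy.exclude_taxids and set(h.subject_taxids) & policy.exclude_taxids:
            continue
        kept.append(h)
    return kept


def hits_to_species_sets(
    hits: Iterable[BlastHit],
    taxonomy: TaxonomyDB,
    exclude_species: frozenset[int] = frozenset(),
    all_queries: Optional[Iterable[str]] = None,
) -> dict[str, set[int]]:
    """Collapse each hit's subject taxids to species-rank ancestors.

    Strain-level taxids map to their species; taxids absent from the
    taxonomy, or with no species-rank ancestor, are counted and skipped
    (database-version skew between the search database and the taxonomy dump
    is expected, not fatal). Queries listed in ``all_queries`` appear in the
    result even with zero mapped species.
    """
    sets: dict[str, set[int]] = {}
    if all_queries is not None:
        for q in all_queries:
            sets[q] = set()
    n_unknown = n_unmapped = n_taxidless = 0
    for h in hits:
        sets.setdefault(h.query_id, set())
        if not h.subject_taxids:
            n_taxidless += 1
            continue
        for t in h.subject_taxids:
            if t not in taxonomy:
                n_unknown += 1
                continue
            sp = taxonomy.species_of(t)
            if sp is None:
                n_unmapped += 1
                continue
            if sp in exclude_species:
                continue
            sets[h.query_id].add(sp)
    if n_unknown or n_unmapped or n_taxidless:
        logger.info(
            "species mapping skipped %d unknown taxids, %d without species "
            "ancestor, %d hits without taxids",
            n_unknown, n_unmapped, n_taxidless,
        )
    return sets
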
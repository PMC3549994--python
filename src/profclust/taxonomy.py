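"""Ranked taxonomy handling: loading dumps, lineage queries, cluster spread tables.

Supports the NCBI taxdump dialect (pipe-delimited ``nodes.dmp``/``names.dmp``)
and a simplified four-column TSV dialect (``tax_id  parent_id  rank  name``)
used for fixtures. Lineage lookups (:func:`TaxonomyDB.species_of`,
:func:`TaxonomyDB.ancestor_at`) are pure and memoized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, TextIO

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .graph_clustering import Clustering
    from .profiles import ProfileSet

__all__ = [
    "TaxonNode",
    "TaxonomyDB",
    "SpeciesUniverse",
    "TaxonomyError",
    "load_taxdump",
    "load_taxonomy_tsv",
    "spread_table",
]

UNPLACED = "unplaced"


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy dump (orphans, duplicates, cycles)."""


@dataclass(frozen=True)
class TaxonNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str

    @property
    def is_root(self) -> bool:
        return self.tax_id == self.parent_id


class TaxonomyDB:
    """In-memory ranked taxonomy with parent links and a children index."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.tax_id in self.nodes:
                raise TaxonomyError(f"duplicate tax_id {node.tax_id}")
            self.nodes[node.tax_id] = node
        self.children: dict[int, list[int]] = {}
        roots = []
        orphans = []
        for node in self.nodes.values():
            if node.is_root:
                roots.append(node.tax_id)
                continue
            if node.parent_id not in self.nodes:
                orphans.append(node.tax_id)
                continue
            self.children.setdefault(node.parent_id, []).append(node.tax_id)
        if orphans:
            raise TaxonomyError(
                "nodes reference absent parents: tax_ids "
                + ", ".join(str(t) for t in sorted(orphans))
            )
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_id: int = roots[0]
        self._check_acyclic()
        self._rank_cache: dict[tuple[int, str], Optional[int]] = {}

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}  # 0 in progress, 1 done
        for start in self.nodes:
            path = []
            t = start
            while t not in state:
                state[t] = 0
                path.append(t)
                node = self.nodes[t]
                if node.is_root:
                    break
                t = node.parent_id
            if state.get(t) == 0 and not self.nodes[t].is_root:
                raise TaxonomyError(f"cycle in parent links involving tax_id {t}")
            for p in path:
                state[p] = 1

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, tax_id: int) -> list[TaxonNode]:
        """Path from ``tax_id`` up to the root, inclusive."""
        if tax_id not in self.nodes:
            raise KeyError(f"unknown tax_id {tax_id}")
        out = []
        t = tax_id
        while True:
            node = self.nodes[t]
            out.append(node)
            if node.is_root:
                return out
            t = node.parent_id

    def ancestor_at(self, tax_id: int, rank: str) -> Optional[int]:
        """Nearest ancestor-or-self with the requested rank, else None."""
        key = (tax_id, rank)
        if key not in self._rank_cache:
            if tax_id not in self.nodes:
                raise KeyError(f"unknown tax_id {tax_id}")
            hit = None
            for node in self.lineage(tax_id):
                if node.rank == rank:
                    hit = node.tax_id
                    break
            self._rank_cache[key] = hit
        return self._rank_cache[key]

    def species_of(self, tax_id: int) -> Optional[int]:
        """Species-rank ancestor-or-self; None if the lineage has no species."""
        return self.ancestor_at(tax_id, "species")

    def name_of(self, tax_id: int) -> str:
        return self.nodes[tax_id].name


@dataclass(frozen=True)
class SpeciesUniverse:
    """Ordered index set of the profile bit-vectors.

    Bit position ``index[s]`` holds species ``species_ids[index[s]]``; the
    ordering is stable across runs given the same input list.
    """

    species_ids: tuple[int, ...]
    index: dict[int, int] = field(compare=False)

    @classmethod
    def from_ids(cls, ids: Iterable[int]) -> "SpeciesUniverse":
        ordered = tuple(ids)
        if len(set(ordered)) != len(ordered):
            raise ValueError("species ids must be unique")
        return cls(species_ids=ordered, index={s: i for i, s in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.species_ids)

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.index


def _as_stream(src) -> TextIO:
    return io.StringIO(src) if isinstance(src, str) else src


def load_taxdump(nodes_stream, names_stream) -> TaxonomyDB:
    """Load the NCBI taxdump dialect (``\\t|\\t``-delimited nodes/names files)."""
    names: dict[int, str] = {}
    for line in _as_stream(names_stream):
        line = line.rstrip("\n").rstrip("\t|")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t|\t")]
        tax_id = int(fields[0])
        name_class = fields[3] if len(fields) > 3 else "scientific name"
        if name_class == "scientific name" or tax_id not in names:
            names[tax_id] = fields[1]
    nodes = []
    for line in _as_stream(nodes_stream):
        line = line.rstrip("\n").rstrip("\t|")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t|\t")]
        tax_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
        nodes.append(TaxonNode(tax_id, parent_id, rank, names.get(tax_id, str(tax_id))))
    return TaxonomyDB(nodes)


def load_taxonomy_tsv(stream) -> TaxonomyDB:
    """Load the simplified fixture dialect: header + tax_id/parent_id/rank/name."""
    handle = _as_stream(stream)
    header = next(handle, "").rstrip("\n").split("\t")
    expected = ["tax_id", "parent_id", "rank", "name"]
    if header != expected:
        raise TaxonomyError(f"expected header {expected}, got {header}")
    nodes = []
    for lineno, line in enumerate(handle, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise TaxonomyError(f"line {lineno}: expected 4 fields, got {len(fields)}")
        try:
            nodes.append(TaxonNode(int(fields[0]), int(fields[1]), fields[2], fields[3]))
        except ValueError as exc:
            raise TaxonomyError(f"line {lineno}: {exc}") from exc
    return TaxonomyDB(nodes)


def write_taxonomy_tsv(db: TaxonomyDB) -> str:
    lines = ["tax_id\tparent_id\trank\tname"]
    for tax_id in sorted(db.nodes):
        n = db.nodes[tax_id]
        lines.append(f"{n.tax_id}\t{n.parent_id}\t{n.rank}\t{n.name}")
    return "\n".join(lines) + "\n"


def spread_table(
    clustering: "Clustering",
    profiles: "ProfileSet",
    db: TaxonomyDB,
    rank: str = "phylum",
    per_species: bool = False,
) -> pd.DataFrame:
    """Taxonomic spread of each cluster at a rank, normalized by cluster size.

    Default convention: cell(group, cluster) = fraction of the cluster's
    proteins with at least one homologue-bearing species inside the group.
    With ``per_species=True`` the cell instead averages, over cluster members,
    the number of the member's species that fall in the group.

    Species without an ancestor at ``rank`` are tallied under ``"unplaced"``.
    """
    # map each universe species to its group label once
    group_of: dict[int, str] = {}
    for s in profiles.universe.species_ids:
        anc = db.ancestor_at(s, rank) if s in db else None
        group_of[s] = db.name_of(anc) if anc is not None else UNPLACED

    clusters = clustering.clusters()
    data: dict[str, dict[str, float]] = {}
    for label, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {label!r} is empty")
        col: dict[str, float] = {}
        for pid in members:
            groups_hit = [group_of[s] for s in profiles.species_of_protein(pid)]
            if per_species:
                for g in groups_hit:
                    col[g] = col.get(g, 0.0) + 1.0
            else:
                for g in set(groups_hit):
                    col[g] = col.get(g, 0.0) + 1.0
        data[label] = {g: v / len(members) for g, v in col.items()}

    all_groups = sorted({g for col in data.values() for g in col})
    table = pd.DataFrame(
        {label: [data[label].get(g, 0.0) for g in all_groups] for label in data},
        index=all_groups,
    )
    table.index.name = rank
    return table
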
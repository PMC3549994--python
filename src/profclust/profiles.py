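"""Bit-vector phylogenetic profiles and the gated scalar-product similarity.

A phylogenetic profile is a presence/absence vector ``L`` over a fixed,
ordered species universe: bit ``p`` is set when the protein has at least one
accepted homology hit in species ``universe.species_ids[p]``. The scalar
product ``D = popcount(L_i AND L_j)`` counts species common to two profiles,
and the similarity ``S(i, j)`` normalizes ``D`` by profile popcounts
(``N_i``, ``N_j``). Pairs are only compared when the smaller popcount is at
least 60% of the larger (the length gate), which prevents the near-universal
presence of most proteins in a clade from washing out cluster resolution.

Bits are stored packed, eight species per byte, and all pairwise scalar
products are computed with vectorized popcounts on the packed matrix.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .taxonomy import SpeciesUniverse

__all__ = [
    "PhyloProfile",
    "ProfileSet",
    "NORMS",
    "build_profiles",
    "shared_count",
    "similarity",
    "length_gate",
    "similarity_graph",
]

logger = logging.getLogger(__name__)

NORMS = ("min", "geometric", "jaccard")


class PhyloProfile:
    """One protein's presence/absence bit-vector plus its popcount ``N``."""

    __slots__ = ("protein_id", "bits", "width", "N")

    def __init__(self, protein_id: str, bits: np.ndarray, width: int):
        if bits.dtype != np.uint8 or bits.ndim != 1:
            raise ValueError("bits must be a 1-d packed uint8 array")
        if bits.size != (width + 7) // 8:
            raise ValueError(f"packed size {bits.size} inconsistent with width {width}")
        self.protein_id = protein_id
        self.bits = bits
        self.width = width
        self.N = int(np.bitwise_count(bits).sum())

    @classmethod
    def from_species_set(
        cls, protein_id: str, species: Iterable[int], universe: SpeciesUniverse
    ) -> "PhyloProfile":
        mask = np.zeros(len(universe), dtype=bool)
        dropped = 0
        for s in species:
            pos = universe.index.get(s)
            if pos is None:
                dropped += 1
            else:
                mask[pos] = True
        if dropped:
            logger.info("%s: %d species outside the universe dropped", protein_id, dropped)
        return cls(protein_id, np.packbits(mask), len(universe))

    def species_ids(self, universe: SpeciesUniverse) -> set[int]:
        mask = np.unpackbits(self.bits, count=self.width).astype(bool)
        return {universe.species_ids[i] for i in np.flatnonzero(mask)}

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloProfile({self.protein_id!r}, N={self.N}, width={self.width})"


def shared_count(a: PhyloProfile, b: PhyloProfile) -> int:
    """Scalar product D: number of species common to both profiles."""
    if a.width != b.width:
        raise ValueError(f"universe mismatch: widths {a.width} != {b.width}")
    return int(np.bitwise_count(a.bits & b.bits).sum())


def _normalize(D: float, Na: int, Nb: int, norm: str) -> float:
    if norm == "min":
        m = min(Na, Nb)
        return D / m if m else 0.0
    if norm == "geometric":
        return D / np.sqrt(Na * Nb) if Na and Nb else 0.0
    if norm == "jaccard":
        u = Na + Nb - D
        return D / u if u else 0.0
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


def similarity(a: PhyloProfile, b: PhyloProfile, norm: str = "min") -> float:
    """Similarity S(i, j) in [0, 1]; 0 whenever either profile is empty.

    ``min`` (default): D / min(N_a, N_b); ``geometric``: D / sqrt(N_a N_b);
    ``jaccard``: D / |union|.
    """
    D = shared_count(a, b)
    if min(a.N, b.N) == 0:
        return 0.0
    return float(_normalize(D, a.N, b.N, norm))


def length_gate(a: PhyloProfile, b: PhyloProfile, min_ratio: float = 0.6) -> bool:
    """True iff the smaller popcount is >= ``min_ratio`` of the larger.

    Inclusive at the boundary (a 60-vs-100 pair passes at the default 0.6).
    A pair with both profiles empty gates False.
    """
    if a.width != b.width:
        raise ValueError("universe mismatch")
    mn, mx = sorted((a.N, b.N))
    if mx == 0:
        return False
    return mn / mx >= min_ratio


class ProfileSet:
    """Profiles over one shared universe, with optional per-protein metadata.

    ``metadata`` is a DataFrame indexed by protein id; conventional columns
    are ``length`` (residues) and ``disease_mutation`` (bool).
    """

    def __init__(
        self,
        universe: SpeciesUniverse,
        profiles: Iterable[PhyloProfile],
        metadata: Optional[pd.DataFrame] = None,
    ):
        self.universe = universe
        self.profiles: list[PhyloProfile] = list(profiles)
        self._index: dict[str, int] = {}
        for i, p in enumerate(self.profiles):
            if p.protein_id in self._index:
                raise ValueError(f"duplicate protein id {p.protein_id!r}")
            if p.width != len(universe):
                raise ValueError(f"{p.protein_id}: width {p.width} != universe {len(universe)}")
            self._index[p.protein_id] = i
        if metadata is None:
            metadata = pd.DataFrame(index=pd.Index(self.protein_ids, name="protein_id"))
        self.metadata = metadata

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, key) -> PhyloProfile:
        if isinstance(key, str):
            return self.profiles[self._index[key]]
        return self.profiles[key]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def species_of_protein(self, protein_id: str) -> set[int]:
        return self[protein_id].species_ids(self.universe)

    def packed_matrix(self) -> np.ndarray:
        return np.vstack([p.bits for p in self.profiles]) if self.profiles else np.zeros(
            (0, (len(self.universe) + 7) // 8), dtype=np.uint8
        )

    # -- serialization ------------------------------------------------------

    def to_matrix_tsv(self) -> str:
        """Proteins x species 0/1 matrix with a species-id header column."""
        header = "protein_id\t" + "\t".join(str(s) for s in self.universe.species_ids)
        lines = [header]
        for p in self.profiles:
            mask = np.unpackbits(p.bits, count=p.width)
            lines.append(p.protein_id + "\t" + "\t".join(map(str, mask)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_matrix_tsv(cls, text, metadata: Optional[pd.DataFrame] = None) -> "ProfileSet":
        handle = io.StringIO(text) if isinstance(text, str) else text
        header = next(handle).rstrip("\n").split("\t")
        universe = SpeciesUniverse.from_ids(int(s) for s in header[1:])
        profiles = []
        for line in handle:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            mask = np.array([int(x) for x in fields[1:]], dtype=bool)
            profiles.append(PhyloProfile(fields[0], np.packbits(mask), len(universe)))
        return cls(universe, profiles, metadata)

    def to_hex_tsv(self) -> str:
        """Compact format: protein_id, N, hex-encoded packed bits."""
        lines = [f"#universe\t{','.join(str(s) for s in self.universe.species_ids)}"]
        lines.append("protein_id\tN\tbits_hex")
        for p in self.profiles:
            lines.append(f"{p.protein_id}\t{p.N}\t{p.bits.tobytes().hex()}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_hex_tsv(cls, text, metadata: Optional[pd.DataFrame] = None) -> "ProfileSet":
        handle = io.StringIO(text) if isinstance(text, str) else text
        first = next(handle).rstrip("\n")
        if not first.startswith("#universe\t"):
            raise ValueError("missing #universe header line")
        universe = SpeciesUniverse.from_ids(
            int(s) for s in first.split("\t", 1)[1].split(",") if s
        )
        next(handle)  # column header
        width = len(universe)
        profiles = []
        for line in handle:
            if not line.strip():
                continue
            pid, n_str, hexbits = line.rstrip("\n").split("\t")
            bits = np.frombuffer(bytes.fromhex(hexbits), dtype=np.uint8)
            prof = PhyloProfile(pid, bits, width)
            if prof.N != int(n_str):
                raise ValueError(f"{pid}: stored N={n_str} != popcount {prof.N}")
            profiles.append(prof)
        return cls(universe, profiles, metadata)


def build_profiles(
    species_sets: Mapping[str, set[int]],
    universe: SpeciesUniverse,
    metadata: Optional[pd.DataFrame] = None,
) -> ProfileSet:
    """One profile per protein; species outside the universe are dropped
    (with a logged count); empty species sets yield all-zero profiles."""
    profiles = [
        PhyloProfile.from_species_set(pid, species, universe)
        for pid, species in species_sets.items()
    ]
    return ProfileSet(universe, profiles, metadata)


@dataclass
class SimilarityEdgeView:
    """Convenience record for an edge in the similarity graph."""

    i: str
    j: str
    D: int
    S: float


def similarity_graph(
    ps: ProfileSet,
    norm: str = "min",
    min_ratio: float = 0.6,
    s_min: float = 0.0,
) -> nx.Graph:
    """Weighted graph of gated pairwise similarities.

    Edge (i, j) is present iff the pair passes the length gate AND
    ``S >= s_min``; ``s_min=0`` gives the clustering-input graph, 0.6 the
    display graph. Every protein is a node, including isolated ones. Edges
    carry integer ``D`` and float ``S`` attributes.
    """
    if norm not in NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    n = len(ps)
    if n < 2:
        raise ValueError("need at least two profiles")
    g = nx.Graph()
    g.add_nodes_from(ps.protein_ids)
    B = ps.packed_matrix()
    N = np.array([p.N for p in ps.profiles], dtype=np.int64)
    ids = ps.protein_ids
    for i in range(n - 1):
        rest = slice(i + 1, n)
        D = np.bitwise_count(B[i] & B[rest]).sum(axis=1).astype(np.int64)
        Nj = N[rest]
        mn = np.minimum(N[i], Nj).astype(np.float64)
        mx = np.maximum(N[i], Nj).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            gate = np.where(mx > 0, mn / mx >= min_ratio, False)
            if norm == "min":
                S = np.where(mn > 0, D / mn, 0.0)
            elif norm == "geometric":
                S = np.where(mn > 0, D / np.sqrt(N[i] * Nj), 0.0)
            else:
                union = N[i] + Nj - D
                S = np.where(union > 0, D / union, 0.0)
        keep = gate & (S >= s_min)
        for off in np.flatnonzero(keep):
            j = i + 1 + off
            g.add_edge(ids[i], ids[j], D=int(D[off]), S=float(S[off]))
    return g
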
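"""Seeded synthetic fixtures: planted-cluster profiles, toy taxonomies, and
matching homology-search tables.

The generator emulates the structure of a real profile-clustered proteome:

* a ranked species universe (root -> superkingdom -> phylum -> species, with
  strain leaves below each species);
* planted protein clusters whose members share a common species pool, with
  per-member presence noise and global bit-flip noise. Pools are nested by
  default (narrow pools inside broad ones), mimicking the nested species
  sets of real clusters: a broad "ubiquitous" cluster, an intermediate
  cluster, and narrow clade-specific clusters;
* unclustered "cloud" proteins with idiosyncratic, independently drawn
  species pools of widely varying breadth;
* a homology-hit table that reproduces the profiles exactly after parsing,
  filtering and species-collapsing, plus injected decoy rows (E-value above
  threshold, subject lengths just outside the 80%/120% window, and
  self-hits to the query organism) that the filters must remove.

Everything is deterministic given ``PlantedSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import PhyloProfile, ProfileSet
from .taxonomy import SpeciesUniverse, TaxonNode, TaxonomyDB

__all__ = [
    "ClusterPlan",
    "PlantedSpec",
    "BlastFixture",
    "generate_taxonomy",
    "generate_profiles",
    "generate_blast_fixture",
]

CLOUD_LABEL = "cloud"


@dataclass(frozen=True)
class ClusterPlan:
    """One planted cluster: member count, species-pool breadth and placement.

    Pools are windows ``[pool_start, pool_start + pool_frac)`` (fractions of
    the universe, wrapping) over one seeded permutation of the species axis,
    so overlap between cluster pools is controlled explicitly by the window
    placement: adjacent tiers share part of their pools (partially nested
    species sets) while breadth tiers stay separated.
    """

    name: str
    size: int
    pool_frac: float
    pool_start: Optional[float] = None  # None: a seeded random start
    presence_prob: float = 0.95
    mean_length: int = 400  # residues; distinct per cluster so length ANOVA has signal

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("cluster size must be positive")
        if not (0 < self.pool_frac <= 1) or not (0 <= self.presence_prob <= 1):
            raise ValueError("pool_frac and presence_prob must be in (0,1] / [0,1]")


# Breadth tiers: consecutive realized popcounts differ by well under the 60%
# length gate between the broadest and narrowest tiers, while the bit-flip
# noise floor (flip_noise * universe) stays small relative to every pool.
# Window placement gives adjacent tiers partially shared pools and the
# narrow tiers a pool slice inside the broad ones.
DEFAULT_CLUSTERS = (
    ClusterPlan("ubiquitous", 50, 0.55, pool_start=0.00, mean_length=350),
    ClusterPlan("broad", 30, 0.35, pool_start=0.45, mean_length=450),
    ClusterPlan("narrow", 20, 0.25, pool_start=0.70, mean_length=650),
    ClusterPlan("very_narrow", 10, 0.18, pool_start=0.87, mean_length=300),
)


@dataclass(frozen=True)
class PlantedSpec:
    """Study conditions for one synthetic instance.

    The default taxonomy is 3 superkingdoms x 4 phyla x 10 species = 120
    species (2 strains each) plus a designated query-organism species that
    is excluded from the profile universe. Planted clusters are 50/30/20/10
    proteins over partially overlapping pools covering 55/35/25/18% of the
    universe, plus 30 cloud proteins whose idiosyncratic pool breadths are
    uniform between 5% and the broadest cluster's breadth.
    """

    taxonomy_shape: tuple[int, int, int] = (3, 4, 10)  # superkingdoms, phyla/sk, species/phylum
    strains_per_species: int = 2
    clusters: tuple[ClusterPlan, ...] = DEFAULT_CLUSTERS
    n_cloud: int = 30
    flip_noise: float = 0.05
    cloud_frac_range: tuple[float, float] = (0.05, 0.45)
    cloud_mean_length: int = 520
    seed: int = 0

    def __post_init__(self):
        if any(x < 1 for x in self.taxonomy_shape):
            raise ValueError("taxonomy_shape entries must be positive")
        if not (0 <= self.flip_noise < 1):
            raise ValueError("flip_noise must be in [0, 1)")

    @property
    def n_species(self) -> int:
        sk, ph, sp = self.taxonomy_shape
        return sk * ph * sp

    @property
    def n_proteins(self) -> int:
        return sum(c.size for c in self.clusters) + self.n_cloud


def generate_taxonomy(spec: PlantedSpec) -> tuple[TaxonomyDB, SpeciesUniverse, int]:
    """Balanced ranked taxonomy; returns (db, universe, query_species_taxid).

    The query organism is an extra species under the first phylum; it is in
    the taxonomy but excluded from the profile universe, so self-hits can be
    generated and must be filtered out.
    """
    sk_n, ph_n, sp_n = spec.taxonomy_shape
    nodes = [TaxonNode(1, 1, "no rank", "root")]
    next_id = 2
    species_ids: list[int] = []
    for a in range(sk_n):
        sk_id = next_id
        next_id += 1
        nodes.append(TaxonNode(sk_id, 1, "superkingdom", f"Superkingdom_{a + 1}"))
        for b in range(ph_n):
            ph_id = next_id
            next_id += 1
            nodes.append(TaxonNode(ph_id, sk_id, "phylum", f"Phylum_{a + 1}_{b + 1}"))
            for c in range(sp_n):
                sp_id = next_id
                next_id += 1
                nodes.append(
                    TaxonNode(sp_id, ph_id, "species", f"Species_{a + 1}_{b + 1}_{c + 1}")
                )
                species_ids.append(sp_id)
                for d in range(spec.strains_per_species):
                    nodes.append(
                        TaxonNode(next_id, sp_id, "strain",
                                  f"Strain_{a + 1}_{b + 1}_{c + 1}_{d + 1}")
                    )
                    next_id += 1
    # the query organism: a species outside the profile universe
    first_phylum = nodes[2].tax_id
    query_sp = next_id
    nodes.append(TaxonNode(query_sp, first_phylum, "species", "Query_organism"))
    next_id += 1
    for d in range(spec.strains_per_species):
        nodes.append(TaxonNode(next_id, query_sp, "strain", f"Query_strain_{d + 1}"))
        next_id += 1
    db = TaxonomyDB(nodes)
    universe = SpeciesUniverse.from_ids(species_ids)
    return db, universe, query_sp


def generate_profiles(
    spec: PlantedSpec, universe: Optional[SpeciesUniverse] = None
) -> tuple[ProfileSet, dict[str, str]]:
    """Planted profiles plus their ground-truth labels.

    Cluster members set each bit of the cluster's pool with
    ``presence_prob``, then every bit of the universe flips with
    ``flip_noise``. Cloud proteins draw an individual random pool whose
    breadth is uniform over ``cloud_frac_range``. Metadata carries a
    per-protein residue length (lognormal around the cluster's mean) and a
    Bernoulli(0.04) disease-mutation flag.
    """
    if universe is None:
        _, universe, _ = generate_taxonomy(spec)
    n = len(universe)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)

    pool_by_cluster: dict[int, np.ndarray] = {}
    for ci, plan in enumerate(spec.clusters):
        size = max(1, round(plan.pool_frac * n))
        start_frac = plan.pool_start if plan.pool_start is not None else rng.uniform()
        start = int(round(start_frac * n)) % n
        members = perm[(start + np.arange(size)) % n]  # wrapping window
        mask = np.zeros(n, dtype=bool)
        mask[members] = True
        pool_by_cluster[ci] = mask

    profiles: list[PhyloProfile] = []
    labels: dict[str, str] = {}
    lengths: list[int] = []
    flags: list[bool] = []
    counter = 0

    def add(mask: np.ndarray, label: str, mean_length: int):
        nonlocal counter
        counter += 1
        pid = f"P{counter:04d}"
        if spec.flip_noise > 0:
            mask = mask ^ (rng.random(n) < spec.flip_noise)
        profiles.append(PhyloProfile(pid, np.packbits(mask), n))
        labels[pid] = label
        lengths.append(max(50, int(rng.lognormal(math.log(mean_length), 0.3))))
        flags.append(bool(rng.random() < 0.04))

    for ci, plan in enumerate(spec.clusters):
        pool = pool_by_cluster[ci]
        for _ in range(plan.size):
            mask = pool & (rng.random(n) < plan.presence_prob)
            add(mask, plan.name, plan.mean_length)
    lo, hi = spec.cloud_frac_range
    for _ in range(spec.n_cloud):
        size = max(1, round(rng.uniform(lo, hi) * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=size, replace=False)] = True
        add(mask, CLOUD_LABEL, spec.cloud_mean_length)

    metadata = pd.DataFrame(
        {"length": lengths, "disease_mutation": flags},
        index=pd.Index([p.protein_id for p in profiles], name="protein_id"),
    )
    return ProfileSet(universe, profiles, metadata), labels


def _length_window(q: int, fmin: float = 0.8, fmax: float = 1.2) -> tuple[int, int]:
    """Smallest/largest subject length passing the inclusive ratio filter."""
    lo = math.ceil(fmin * q)
    while lo / q < fmin:
        lo += 1
    while lo > 1 and (lo - 1) / q >= fmin:
        lo -= 1
    hi = math.floor(fmax * q)
    while hi / q > fmax:
        hi -= 1
    while (hi + 1) / q <= fmax:
        hi += 1
    return lo, hi


@dataclass(frozen=True)
class BlastFixture:
    blast_tab: str            # tabular hits, columns qseqid sseqid evalue qlen slen staxids
    taxid_map: str            # two-column sseqid -> taxid mapping
    n_decoy_evalue: int
    n_decoy_length: int
    n_decoy_self: int
    query_species_taxid: int

    @property
    def n_decoys(self) -> int:
        return self.n_decoy_evalue + self.n_decoy_length + self.n_decoy_self


def generate_blast_fixture(
    ps: ProfileSet, db: TaxonomyDB, spec: PlantedSpec, query_species_taxid: int
) -> BlastFixture:
    """Hit table whose parse -> filter -> species-collapse round trip
    reproduces ``ps`` bit-identically.

    For every set bit one hit row is emitted against a random strain-level
    taxid below the species, with an in-window subject length and an
    E-value at or below 1e-4. Per protein, four decoy rows are injected:
    E-value 0.01, subject just below 80% of the query, subject just above
    120%, and an otherwise-valid self-hit to the query organism's strain.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    lengths = ps.metadata["length"]
    rows: list[str] = []
    mapping: dict[str, int] = {}
    n_ev = n_len = n_self = 0
    acc_counter = 0

    def strain_of(species: int) -> int:
        kids = db.children.get(species, [])
        return int(rng.choice(kids)) if kids else species

    def new_acc(taxid: int) -> str:
        nonlocal acc_counter
        acc_counter += 1
        acc = f"ACC{acc_counter:06d}"
        mapping[acc] = taxid
        return acc

    def row(pid, q, taxid, evalue, slen):
        acc = new_acc(taxid)
        rows.append(f"{pid}\t{acc}\t{evalue:.3g}\t{q}\t{slen}\t{taxid}")

    all_positions = np.arange(len(ps.universe))
    for prof in ps:
        q = int(lengths.loc[prof.protein_id])
        lo, hi = _length_window(q)
        set_pos = np.flatnonzero(np.unpackbits(prof.bits, count=prof.width))
        for pos in set_pos:
            species = ps.universe.species_ids[pos]
            row(
                prof.protein_id, q, strain_of(species),
                10.0 ** rng.uniform(-150, -4), int(rng.integers(lo, hi + 1)),
            )
        # decoys: must all be removed by filtering / species exclusion
        unset = np.setdiff1d(all_positions, set_pos, assume_unique=True)
        decoy_pool = unset if unset.size else all_positions
        decoy_species = ps.universe.species_ids[int(rng.choice(decoy_pool))]
        row(prof.protein_id, q, strain_of(decoy_species), 0.01,
            int(rng.integers(lo, hi + 1)))
        n_ev += 1
        decoy_species2 = ps.universe.species_ids[int(rng.choice(decoy_pool))]
        if lo > 1:
            row(prof.protein_id, q, strain_of(decoy_species2),
                10.0 ** rng.uniform(-150, -4), lo - 1)
            n_len += 1
        row(prof.protein_id, q, strain_of(decoy_species2),
            10.0 ** rng.uniform(-150, -4), hi + 1)
        n_len += 1
        row(prof.protein_id, q, strain_of(query_species_taxid),
            10.0 ** rng.uniform(-150, -4), int(rng.integers(lo, hi + 1)))
        n_self += 1

    blast_tab = "\n".join(rows) + "\n"
    taxid_map = "\n".join(f"{acc}\t{taxid}" for acc, taxid in mapping.items()) + "\n"
    return BlastFixture(blast_tab, taxid_map, n_ev, n_len, n_self, query_species_taxid)
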
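"""Per-cluster summaries and statistical comparisons between clusters.

Covers the downstream analyses of a profile clustering: cluster size and
length summaries, one-way ANOVA of per-protein quantities (length, taxonomy
hit count) across clusters, exact binomial tests of category membership
(e.g. disease-mutation proteins) against a cluster's proteome share,
species-set Venn overlaps between clusters, and annotation-term enrichment
(hypergeometric upper tail with Benjamini-Hochberg FDR correction against
the whole-proteome background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_clustering import CLOUD, Clustering
from .profiles import ProfileSet

__all__ = [
    "ClusterSummary",
    "EnrichmentResult",
    "summarize_clusters",
    "anova_by_cluster",
    "binomial_category_test",
    "species_venn",
    "term_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class ClusterSummary:
    label: str
    n_proteins: int
    pct_of_proteome: float
    mean_protein_length: float  # NaN when lengths are not in the metadata
    hit_count_min: int
    hit_count_median: float
    hit_count_max: int
    species_union: frozenset[int]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    cluster_count: int      # k: annotated proteins inside the cluster
    cluster_size: int       # m
    background_count: int   # K: annotated proteins in the background
    background_size: int    # N
    percent: float          # 100 * k / m
    fold_enrichment: float  # (k/m) / (K/N)
    p_raw: float
    p_adjusted: float


def summarize_clusters(
    clustering: Clustering, profiles: ProfileSet
) -> list[ClusterSummary]:
    """One summary per named cluster plus the cloud; percentages are of the
    whole profile set and sum to 100 up to rounding."""
    total = len(profiles)
    lengths = (
        profiles.metadata["length"] if "length" in profiles.metadata.columns else None
    )
    out = []
    groups = clustering.clusters()
    order = clustering.labels + ([CLOUD] if CLOUD in groups else [])
    for label in order:
        members = groups.get(label, [])
        ns = [profiles[pid].N for pid in members]
        union: set[int] = set()
        for pid in members:
            union |= profiles.species_of_protein(pid)
        mean_len = (
            float(np.mean([lengths.loc[pid] for pid in members]))
            if lengths is not None and members
            else float("nan")
        )
        out.append(
            ClusterSummary(
                label=label,
                n_proteins=len(members),
                pct_of_proteome=100.0 * len(members) / total if total else 0.0,
                mean_protein_length=mean_len,
                hit_count_min=int(min(ns)) if ns else 0,
                hit_count_median=float(np.median(ns)) if ns else 0.0,
                hit_count_max=int(max(ns)) if ns else 0,
                species_union=frozenset(union),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ClusterSummary]) -> pd.DataFrame:
    rows = [
        {
            "cluster": s.label,
            "n_proteins": s.n_proteins,
            "pct_of_proteome": s.pct_of_proteome,
            "mean_protein_length": s.mean_protein_length,
            "hit_count_min": s.hit_count_min,
            "hit_count_median": s.hit_count_median,
            "hit_count_max": s.hit_count_max,
            "n_species": len(s.species_union),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).set_index("cluster")


def anova_by_cluster(
    clustering: Clustering, values: Mapping[str, float]
) -> tuple[float, float, dict[str, float]]:
    """One-way fixed-effects ANOVA of a per-protein quantity across clusters
    (cloud included as a group). Returns (F, p, per-group means)."""
    groups: dict[str, list[float]] = {}
    for pid, label in clustering.assignment.items():
        if pid in values:
            groups.setdefault(label, []).append(float(values[pid]))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    labels = sorted(groups)
    f_stat, p = stats.f_oneway(*(groups[g] for g in labels))
    means = {g: float(np.mean(groups[g])) for g in labels}
    return float(f_stat), float(p), means


def binomial_category_test(
    k: int, n: int, p0: float, alternative: str = "two-sided"
) -> float:
    """Exact binomial tail probability for k category members out of n when
    each falls in the cluster with probability ``p0`` (the cluster's share
    of the proteome). ``alternative`` is ``less``, ``greater`` or
    ``two-sided`` (small-p aggregation)."""
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    return float(stats.binomtest(k, n, p0, alternative=alt).pvalue)


def species_venn(
    clustering: Clustering,
    profiles: ProfileSet,
    clusters: list[str],
    max_sets: int = 4,
) -> dict[frozenset[str], int]:
    """Exclusive region counts of the clusters' species unions.

    For c requested clusters every one of the 2^c - 1 regions is keyed by
    the frozenset of cluster labels whose sets contain the species; regions
    partition the union, so counts sum to the union's size.
    """
    if len(clusters) > max_sets:
        raise ValueError(f"at most {max_sets} clusters supported, got {len(clusters)}")
    members = clustering.clusters()
    unions: dict[str, set[int]] = {}
    for label in clusters:
        if not members.get(label):
            raise ValueError(f"cluster {label!r} is empty or unknown")
        u: set[int] = set()
        for pid in members[label]:
            u |= profiles.species_of_protein(pid)
        unions[label] = u
    all_species = set().union(*unions.values()) if unions else set()
    regions: dict[frozenset[str], int] = {}
    for labels_subset in _nonempty_subsets(clusters):
        regions[frozenset(labels_subset)] = 0
    for s in all_species:
        in_labels = frozenset(lbl for lbl in clusters if s in unions[lbl])
        regions[in_labels] += 1
    return regions


def _nonempty_subsets(items: list[str]):
    n = len(items)
    for mask in range(1, 1 << n):
        yield [items[i] for i in range(n) if mask >> i & 1]


def venn_to_tsv(regions: Mapping[frozenset, int], clusters: list[str]) -> str:
    """Regions keyed by a membership bitmask over ``clusters`` order."""
    lines = ["region\tclusters\tn_species"]
    for labels, count in sorted(regions.items(), key=lambda kv: sorted(kv[0])):
        mask = "".join("1" if c in labels else "0" for c in clusters)
        lines.append(f"{mask}\t{'&'.join(sorted(labels))}\t{count}")
    return "\n".join(lines) + "\n"


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(
    clustering: Clustering,
    cluster_label: str,
    annotations: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Annotation-term enrichment of one cluster against a background set.

    For each term present in the cluster: hypergeometric upper-tail p-value
    of drawing k or more annotated proteins in a cluster of size m from a
    background of size N containing K annotated proteins; fold enrichment
    (k/m)/(K/N); BH adjustment across the cluster's tested terms. Sorted by
    adjusted then raw p.
    """
    if not background:
        raise ValueError("empty background set")
    members = set(clustering.members(cluster_label))
    if not members <= background:
        raise ValueError("cluster is not a subset of the background")
    m = len(members)
    N = len(background)
    term_in_cluster: dict[str, int] = {}
    term_in_background: dict[str, int] = {}
    for pid in background:
        for term in annotations.get(pid, ()):
            term_in_background[term] = term_in_background.get(term, 0) + 1
            if pid in members:
                term_in_cluster[term] = term_in_cluster.get(term, 0) + 1
    terms = sorted(term_in_cluster)
    raw = []
    for term in terms:
        k = term_in_cluster[term]
        K = term_in_background[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        raw.append((term, k, K, p))
    adjusted = bh_adjust([r[3] for r in raw])
    results = [
        EnrichmentResult(
            term=term,
            cluster_count=k,
            cluster_size=m,
            background_count=K,
            background_size=N,
            percent=100.0 * k / m,
            fold_enrichment=(k / m) / (K / N),
            p_raw=p,
            p_adjusted=float(min(1.0, p_adj)),
        )
        for (term, k, K, p), p_adj in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.cluster_count,
                "m": r.cluster_size,
                "K": r.background_count,
                "N": r.background_size,
                "percent": r.percent,
                "fold_enrichment": r.fold_enrichment,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
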
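"""Force-directed layout and convex cluster calling on the similarity graph.

The layout is a Fruchterman-Reingold scheme: every node pair repels with
force k^2/d, every edge attracts with force S * d^2 / k (the similarity S in
[0, 1] acts directly as the attraction strength), per-step displacement is
capped by a temperature that decays geometrically. The layout is used for
visualization and sanity checks only.

Cluster calling is deliberately layout-independent: a protein joins the
cluster to which its average attraction (mean similarity to current
members, absent edges counting 0) exceeds the dataset-wide mean pairwise
similarity by a set number of standard deviations (default 0.5 SD).
Proteins attracted to no cluster strongly enough form the unclustered
"cloud". Named clusters are labelled A, B, C, ... in descending size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np

__all__ = [
    "CLOUD",
    "LayoutParams",
    "LayoutState",
    "Clustering",
    "init_layout",
    "fr_step",
    "run_layout",
    "convex_clusters",
    "write_clans",
    "read_clans",
]

CLOUD = "CLOUD"


@dataclass(frozen=True)
class LayoutParams:
    """Layout knobs; defaults converge robustly on graphs up to ~5000 nodes."""

    dims: int = 3
    iterations: int = 1000
    initial_temperature: float = 0.1
    cooling: float = 0.99
    repulsion_constant: float = 1.0
    attraction_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.initial_temperature <= 0 or self.repulsion_constant <= 0:
            raise ValueError("temperature and repulsion constant must be positive")


@dataclass
class LayoutState:
    node_ids: tuple[str, ...]
    positions: np.ndarray  # (n, dims)
    temperature: float
    step_index: int
    rng: np.random.Generator

    def position_of(self, node_id: str) -> np.ndarray:
        return self.positions[self.node_ids.index(node_id)]


def init_layout(graph: nx.Graph, params: LayoutParams) -> LayoutState:
    """Seeded uniform placement in the unit box; node order is sorted ids so
    the layout is invariant to graph insertion order."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    node_ids = tuple(sorted(graph.nodes))
    rng = np.random.default_rng(params.seed)
    positions = rng.uniform(0.0, 1.0, size=(len(node_ids), params.dims))
    return LayoutState(node_ids, positions, params.initial_temperature, 0, rng)


def _edge_arrays(graph: nx.Graph, node_ids: tuple[str, ...]):
    idx = {nid: i for i, nid in enumerate(node_ids)}
    ii, jj, ss = [], [], []
    for u, v, d in graph.edges(data=True):
        ii.append(idx[u])
        jj.append(idx[v])
        ss.append(float(d.get("S", 1.0)))
    return np.array(ii, dtype=np.intp), np.array(jj, dtype=np.intp), np.array(ss)


def fr_step(state: LayoutState, graph: nx.Graph, params: LayoutParams) -> LayoutState:
    """One annealing iteration; returns a new state with cooled temperature.

    Coincident nodes are jittered by a seeded epsilon before force
    evaluation, so distances are always positive.
    """
    pos = state.positions.copy()
    n = pos.shape[0]
    k = params.repulsion_constant * (1.0 / max(n, 1)) ** (1.0 / params.dims)

    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    clash = (dist < 1e-9) & ~np.eye(n, dtype=bool)
    if clash.any():
        jitter = state.rng.normal(scale=1e-6 * max(k, 1e-9), size=pos.shape)
        pos = pos + jitter
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    dist = np.maximum(dist, 1e-12)

    # repulsion: k^2 / d along the separating direction
    rep = (k * k) / (dist * dist)  # magnitude/d, combined with raw diff below
    disp = (diff * rep[:, :, None]).sum(axis=1)

    # attraction along edges: S * d^2 / k
    ii, jj, ss = _edge_arrays(graph, state.node_ids)
    if ii.size:
        evec = pos[ii] - pos[jj]
        edist = np.maximum(np.linalg.norm(evec, axis=-1), 1e-12)
        f = params.attraction_scale * ss * edist * edist / k  # force magnitude
        pull = evec * (f / edist)[:, None]
        np.subtract.at(disp, ii, pull)
        np.add.at(disp, jj, pull)

    # cap each node's displacement by the temperature
    norms = np.maximum(np.linalg.norm(disp, axis=-1), 1e-12)
    scale = np.minimum(norms, state.temperature) / norms
    pos = pos + disp * scale[:, None]
    if not np.all(np.isfinite(pos)):
        raise FloatingPointError("non-finite coordinates in layout step")
    return LayoutState(
        state.node_ids, pos, state.temperature * params.cooling,
        state.step_index + 1, state.rng,
    )


def run_layout(graph: nx.Graph, params: LayoutParams) -> LayoutState:
    """Apply :func:`fr_step` for ``params.iterations`` steps; deterministic
    for a given seed."""
    state = init_layout(graph, params)
    for _ in range(params.iterations):
        state = fr_step(state, graph, params)
    return state


# ---------------------------------------------------------------------------
# convex clustering
# ---------------------------------------------------------------------------


def _label_sequence(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — spreadsheet-style labels."""
    labels = []
    for i in range(n):
        s, x = "", i
        while True:
            s = chr(ord("A") + x % 26) + s
            x = x // 26 - 1
            if x < 0:
                break
        labels.append(s)
    return labels


@dataclass(frozen=True)
class Clustering:
    """Assignment of each protein to one named cluster or the cloud."""

    assignment: Mapping[str, str]

    def clusters(self, include_cloud: bool = True) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, label in self.assignment.items():
            out.setdefault(label, []).append(pid)
        for members in out.values():
            members.sort()
        if not include_cloud:
            out.pop(CLOUD, None)
        return out

    @property
    def labels(self) -> list[str]:
        """Named cluster labels, excluding the cloud, in label order."""
        return sorted(set(self.assignment.values()) - {CLOUD})

    def members(self, label: str) -> list[str]:
        return self.clusters().get(label, [])

    def to_tsv(self) -> str:
        lines = ["protein_id\tcluster"]
        for pid in sorted(self.assignment):
            lines.append(f"{pid}\t{self.assignment[pid]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Clustering":
        lines = text.strip().split("\n")
        assignment = {}
        for line in lines[1:]:
            pid, label = line.split("\t")
            assignment[pid] = label
        return cls(assignment)


def convex_clusters(
    graph: nx.Graph,
    min_attraction_sd: float = 0.5,
    min_cluster_size: int = 2,
    max_rounds: int = 100,
) -> Clustering:
    """CLANS-style convex cluster calling on gated similarities.

    The attraction of protein i to cluster C is the mean of S(i, j) over
    members j != i (absent edges contribute 0). The admission threshold is
    mu + ``min_attraction_sd`` * sigma, where mu and sigma are the mean and
    standard deviation of all gated pairwise similarities (the edge weights
    of the s_min=0 graph). Seed clusters are the connected components of the
    graph restricted to edges at or above the threshold; membership is then
    iterated synchronously to a fixpoint. Admission is inclusive (a(i, C)
    equal to the threshold keeps the protein), so the degenerate
    zero-variance case — e.g. disjoint cliques with uniform similarity —
    yields the cliques rather than an empty clustering. Clusters below
    ``min_cluster_size`` dissolve into the cloud.

    Deterministic, and invariant to protein input order: ties between
    clusters with equal attraction go to the larger cluster, then to the one
    with the lexicographically smallest member.
    """
    nodes = sorted(graph.nodes)
    svals = np.array([d["S"] for _, _, d in graph.edges(data=True)], dtype=float)
    if svals.size == 0:
        return Clustering({n: CLOUD for n in nodes})
    mu = float(svals.mean())
    sigma = float(svals.std())  # population SD over the dataset's pair values
    thr = mu + min_attraction_sd * sigma

    strong = nx.Graph()
    strong.add_edges_from(
        (u, v) for u, v, d in graph.edges(data=True) if d["S"] >= thr
    )
    clusters: list[set[str]] = [set(c) for c in nx.connected_components(strong)]
    if not clusters:
        return Clustering({n: CLOUD for n in nodes})

    adj = {n: {} for n in nodes}
    for u, v, d in graph.edges(data=True):
        adj[u][v] = d["S"]
        adj[v][u] = d["S"]

    def sort_key(c: set[str]):
        return (-len(c), min(c))

    for _ in range(max_rounds):
        clusters.sort(key=sort_key)
        moved: dict[int, set[str]] = {}
        for node in nodes:
            best_ci, best_a = None, -1.0
            sims = adj[node]
            for ci, members in enumerate(clusters):
                denom = len(members) - (1 if node in members else 0)
                if denom == 0:
                    continue
                a = sum(sims.get(m, 0.0) for m in members if m != node) / denom
                if a > best_a + 1e-15:  # earlier cluster wins ties (size, then label)
                    best_ci, best_a = ci, a
            if best_ci is not None and best_a >= thr:
                moved.setdefault(best_ci, set()).add(node)
        new_clusters = [members for members in moved.values() if members]
        if {frozenset(c) for c in new_clusters} == {frozenset(c) for c in clusters}:
            clusters = new_clusters
            break
        clusters = new_clusters
        if not clusters:
            break

    clusters = [c for c in clusters if len(c) >= min_cluster_size]
    clusters.sort(key=sort_key)
    labels = _label_sequence(len(clusters))
    final: dict[str, str] = {n: CLOUD for n in nodes}
    for label, members in zip(labels, clusters):
        for m in members:
            final[m] = label
    return Clustering(final)


# ---------------------------------------------------------------------------
# CLANS run-file interchange
# ---------------------------------------------------------------------------


def write_clans(
    graph: nx.Graph,
    layout: LayoutState,
    path,
    sequences: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a CLANS-style run file (<seq>, <pos>, <hsp> blocks).

    The ``<hsp>`` value field stores the similarity S directly (profile
    similarities, not E-values, drive the attraction here). Stub 'X'
    sequences are emitted when no sequences are supplied.
    """
    node_ids = layout.node_ids
    if set(node_ids) != set(graph.nodes):
        raise ValueError("layout nodes do not match graph nodes")
    if len(node_ids) == 0:
        raise ValueError("empty graph")
    idx = {nid: i for i, nid in enumerate(node_ids)}
    pos = layout.positions
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(node_ids))])
    lines = [f"sequences={len(node_ids)}"]
    lines.append("<seq>")
    for nid in node_ids:
        seq = sequences.get(nid, "X") if sequences else "X"
        lines.append(f">{nid}")
        lines.append(seq)
    lines.append("</seq>")
    lines.append("<pos>")
    for i, nid in enumerate(node_ids):
        lines.append(f"{i} {float(pos[i, 0])!r} {float(pos[i, 1])!r} {float(pos[i, 2])!r}")
    lines.append("</pos>")
    lines.append("<hsp>")
    for u, v, d in graph.edges(data=True):
        i, j = idx[u], idx[v]
        if i > j:
            i, j = j, i
        lines.append(f"{i} {j}:{float(d['S'])!r}")
    lines.append("</hsp>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_clans(path) -> tuple[nx.Graph, LayoutState]:
    """Read a file written by :func:`write_clans`; inverse up to edge order."""
    with open(path) as fh:
        text = fh.read()
    lines = text.strip("\n").split("\n")
    if not lines[0].startswith("sequences="):
        raise ValueError("not a CLANS run file: missing sequences= header")
    n = int(lines[0].split("=", 1)[1])

    def block(tag: str) -> list[str]:
        start = lines.index(f"<{tag}>") + 1
        end = lines.index(f"</{tag}>")
        return lines[start:end]

    node_ids = [ln[1:] for ln in block("seq") if ln.startswith(">")]
    if len(node_ids) != n:
        raise ValueError(f"sequences={n} but {len(node_ids)} seq entries")
    positions = np.zeros((n, 3))
    for ln in block("pos"):
        parts = ln.split()
        positions[int(parts[0])] = [float(x) for x in parts[1:4]]
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for ln in block("hsp"):
        left, val = ln.split(":", 1)
        i, j = (int(x) for x in left.split())
        graph.add_edge(node_ids[i], node_ids[j], S=float(val))
    state = LayoutState(
        tuple(node_ids), positions, 0.0, 0, np.random.default_rng(0)
    )
    return graph, state
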
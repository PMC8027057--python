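"""Co-occurrence network, cohesive-block decomposition and partnership counts.

Significant positive correlations become an undirected weighted graph; the
strongest edges (99th percentile of coefficients at survey scale) are kept and
the graph is decomposed into cohesive blocks (Moody-White structural cohesion):
nested node subsets whose internal vertex connectivity exceeds that of their
parent. ANME-SRB partnerships are then summarized by counting, for each
(ANME subtype, SRB clade) cell, the network edges between the two clades that
lie inside a nested (non-root) block — the quantity a chord diagram displays.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ParameterError
from .otu import ANME_CLADES, SRB_CLADES

logger = logging.getLogger(__name__)


def percentile_filter(edges: pd.DataFrame, q: float = 0.99) -> pd.DataFrame:
    """Keep the ceil((1-q)*N) strongest edges by weight, plus boundary ties.

    ``edges`` must have a ``rho`` (weight) column. An empty input returns an
    empty output with a warning.
    """
    if not 0.0 <= q < 1.0:
        raise ParameterError("q must be in [0, 1)")
    if len(edges) == 0:
        logger.warning("percentile_filter: empty edge list")
        return edges.copy()
    # round before ceil: (1 - 0.99) * 200 is 2.0000000000000018 in binary
    n_keep = max(1, math.ceil(round((1.0 - q) * len(edges), 9)))
    weights = np.sort(edges["rho"].to_numpy())[::-1]
    threshold = weights[n_keep - 1]
    kept = edges[edges["rho"] >= threshold].reset_index(drop=True)
    logger.info("percentile_filter: kept %d of %d edges (q=%.3g)", len(kept), len(edges), q)
    return kept


def build_network(edges: pd.DataFrame, node_metadata: pd.DataFrame | None = None) -> nx.Graph:
    """Simple undirected graph from an (otu_i, otu_j, rho) edge list.

    Self-pairs are dropped with a warning; duplicate edges with conflicting
    weights are an error; non-positive weights are dropped (the network models
    positive co-occurrence). ``node_metadata`` (indexed by OTU id, e.g. columns
    clade/genus/mean_count) is attached to nodes.
    """
    G = nx.Graph()
    for row in edges.itertuples(index=False):
        u, v, w = row.otu_i, row.otu_j, float(row.rho)
        if u == v:
            logger.warning("build_network: dropping self-pair (%s, %s)", u, v)
            continue
        if w <= 0:
            logger.warning("build_network: dropping non-positive edge (%s, %s, %g)", u, v, w)
            continue
        if G.has_edge(u, v):
            if not math.isclose(G[u][v]["weight"], w, rel_tol=1e-9):
                raise ParameterError(f"duplicate edge ({u}, {v}) with conflicting weights")
            continue
        G.add_edge(u, v, weight=w)
    if node_metadata is not None:
        for node in G.nodes:
            if node in node_metadata.index:
                G.nodes[node].update(node_metadata.loc[node].to_dict())
    return G


# ---------------------------------------------------------------------------
# Cohesive blocks (Moody-White)


@dataclass(frozen=True)
class Block:
    id: int
    parent_id: int | None
    k: int
    nodes: frozenset


@dataclass
class BlockTree:
    """Rooted forest of cohesive blocks; roots are the connected components."""

    blocks: list[Block] = field(default_factory=list)

    @property
    def roots(self) -> list[Block]:
        return [b for b in self.blocks if b.parent_id is None]

    def children(self, block_id: int) -> list[Block]:
        return [b for b in self.blocks if b.parent_id == block_id]

    def parent(self, block: Block) -> Block | None:
        if block.parent_id is None:
            return None
        return next(b for b in self.blocks if b.id == block.parent_id)

    def depth(self, block: Block) -> int:
        d, b = 0, block
        while b.parent_id is not None:
            b = self.parent(b)
            d += 1
        return d

    def nested_blocks(self) -> list[Block]:
        """All non-root blocks."""
        return [b for b in self.blocks if b.parent_id is not None]

    def validate(self) -> None:
        for b in self.blocks:
            p = self.parent(b)
            if p is not None:
                if not b.nodes < p.nodes:
                    raise AssertionError("child node set must be a strict subset of parent")
                if not b.k > p.k:
                    raise AssertionError("child connectivity must exceed parent connectivity")

    def to_json(self) -> str:
        return json.dumps(
            [
                {"id": b.id, "parent_id": b.parent_id, "k": b.k, "nodes": sorted(map(str, b.nodes))}
                for b in self.blocks
            ]
        )


def _connectivity(G: nx.Graph) -> int:
    n = G.number_of_nodes()
    if n <= 1:
        return 0
    return nx.node_connectivity(G)


def _is_complete(G: nx.Graph) -> bool:
    n = G.number_of_nodes()
    return G.number_of_edges() == n * (n - 1) // 2


def cohesive_blocks(G: nx.Graph) -> BlockTree:
    """Moody-White recursion: nested subsets of increasing vertex connectivity.

    For each component: compute connectivity k, remove one minimum vertex cut,
    and recurse on every resulting component together with the cut. A candidate
    is emitted as a block when its connectivity exceeds its parent block's.
    Emitted blocks contained in another block of equal or higher connectivity
    are pruned, and the hierarchy is rebuilt by node-set containment, so the
    output does not depend on which minimum cut was chosen.
    """
    candidates: list[tuple[frozenset, int]] = []
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        k = _connectivity(sub)
        candidates.append((frozenset(comp), k))
        _recurse(sub, k, candidates, seen=set())
    return _assemble_tree(candidates, [frozenset(c) for c in nx.connected_components(G)])


def _recurse(sub: nx.Graph, parent_k: int, candidates: list, seen: set) -> None:
    if sub.number_of_nodes() <= 2 or _is_complete(sub):
        return
    key = (frozenset(sub.nodes), parent_k)
    if key in seen:
        return
    seen.add(key)
    if _connectivity(sub) == 0:
        parts = [set(c) for c in nx.connected_components(sub)]
        cut: set = set()
    else:
        cut = set(nx.minimum_node_cut(sub))
        rest = sub.subgraph(set(sub.nodes) - cut)
        parts = [set(c) for c in nx.connected_components(rest)]
    for part in parts:
        cand_nodes = part | cut
        if cand_nodes == set(sub.nodes):
            continue
        cand = sub.subgraph(cand_nodes)
        k = _connectivity(cand)
        if k > parent_k:
            candidates.append((frozenset(cand_nodes), k))
            _recurse(cand, k, candidates, seen)
        else:
            _recurse(cand, parent_k, candidates, seen)


def _assemble_tree(candidates: list[tuple[frozenset, int]], roots: list[frozenset]) -> BlockTree:
    # dedupe by node set (same set always has the same connectivity)
    uniq: dict[frozenset, int] = {}
    for nodes, k in candidates:
        uniq[nodes] = max(k, uniq.get(nodes, 0))
    # prune: drop a block strictly contained in another with >= connectivity
    items = sorted(uniq.items(), key=lambda it: -len(it[0]))
    kept: list[tuple[frozenset, int]] = []
    for nodes, k in items:
        absorbed = any(nodes < other and k <= ok for other, ok in uniq.items() if other != nodes)
        if absorbed and nodes not in roots:
            continue
        kept.append((nodes, k))
    # parent = smallest strict superset among kept (ties: higher k)
    tree = BlockTree()
    order = sorted(kept, key=lambda it: -len(it[0]))
    ids: dict[frozenset, int] = {}
    for nodes, k in order:
        supers = [(o, ok) for o, ok in order if nodes < o]
        parent_id = None
        if supers:
            best = min(supers, key=lambda it: (len(it[0]), -it[1]))
            parent_id = ids[best[0]]
        bid = len(tree.blocks)
        ids[nodes] = bid
        tree.blocks.append(Block(id=bid, parent_id=parent_id, k=k, nodes=nodes))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Layout and partnership summary


def force_layout(G: nx.Graph, seed: int = 0) -> dict:
    """Seeded stress-minimisation layout with edge length proportional to 1/weight.

    Target distances are weighted shortest-path lengths with per-edge length
    1/weight, so stronger correlations draw nodes closer. Visualization only —
    no geometric guarantees beyond determinism under a fixed seed.
    """
    nodes = list(G.nodes)
    if not nodes:
        return {}
    if len(nodes) == 1:
        return {nodes[0]: np.zeros(2)}
    H = G.copy()
    for u, v, d in H.edges(data=True):
        d["length"] = 1.0 / d.get("weight", 1.0)
    targets = dict(nx.all_pairs_dijkstra_path_length(H, weight="length"))
    idx = {n: i for i, n in enumerate(nodes)}
    pairs, dists = [], []
    for u in nodes:
        for v, duv in targets[u].items():
            if idx[v] > idx[u]:
                pairs.append((idx[u], idx[v]))
                dists.append(duv)
    pairs_arr = np.asarray(pairs)
    d_target = np.asarray(dists)
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((len(nodes), 2)) * (np.median(d_target) if len(d_target) else 1.0)

    def stress(flat):
        pos = flat.reshape(-1, 2)
        delta = pos[pairs_arr[:, 0]] - pos[pairs_arr[:, 1]]
        d = np.sqrt((delta**2).sum(axis=1) + 1e-12)
        return float((((d - d_target) / d_target) ** 2).sum())

    res = minimize(stress, x0.ravel(), method="L-BFGS-B")
    pos = res.x.reshape(-1, 2)
    pos = pos - pos.mean(axis=0)
    return {n: pos[i] for n, i in idx.items()}


@dataclass(frozen=True)
class PartnershipMatrix:
    """Edge counts between ANME subtypes (rows) and SRB clades (columns)."""

    counts: pd.DataFrame

    def argmax_cell(self) -> tuple[str, str]:
        arr = self.counts.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        return str(self.counts.index[i]), str(self.counts.columns[j])

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def partnership_matrix(
    tree: BlockTree,
    G: nx.Graph,
    anme_clades: tuple[str, ...] = ANME_CLADES,
    srb_clades: tuple[str, ...] = SRB_CLADES,
) -> PartnershipMatrix:
    """Count ANME-SRB edges lying inside nested cohesive blocks.

    An edge qualifies if one endpoint is an ANME-clade node, the other an
    SRB-clade node, and both endpoints sit inside at least one non-root block.
    Each edge is counted once, attributed at the deepest such block.
    """
    counts = pd.DataFrame(
        np.zeros((len(anme_clades), len(srb_clades)), dtype=int),
        index=list(anme_clades),
        columns=list(srb_clades),
    )
    nested = tree.nested_blocks()
    for u, v in G.edges:
        cu = G.nodes[u].get("clade", "other")
        cv = G.nodes[v].get("clade", "other")
        if cu in anme_clades and cv in srb_clades:
            anme, srb = cu, cv
        elif cv in anme_clades and cu in srb_clades:
            anme, srb = cv, cu
        else:
            continue
        if not any(u in b.nodes and v in b.nodes for b in nested):
            continue
        # each qualifying edge counted exactly once (at its deepest block)
        counts.loc[anme, srb] += 1
    return PartnershipMatrix(counts=counts)


def write_network(G: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    if edgelist_path is not None:
        rows = [
            {"otu_i": u, "otu_j": v, "rho": d.get("weight", 1.0)} for u, v, d in G.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(edgelist_path, index=False)
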
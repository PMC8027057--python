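"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: connectivity by
exhaustive vertex-cut search, the basis-variance system by its closed-form
inverse, and cohesive blocks by a recursion that explores every minimum cut.
"""

import itertools

import networkx as nx
import numpy as np


def brute_connectivity(G: nx.Graph) -> int:
    n = G.number_of_nodes()
    if n <= 1 or not nx.is_connected(G):
        return 0
    if G.number_of_edges() == n * (n - 1) // 2:
        return n - 1
    nodes = list(G.nodes)
    for k in range(1, n - 1):
        for cut in itertools.combinations(nodes, k):
            H = G.copy()
            H.remove_nodes_from(cut)
            if H.number_of_nodes() and not nx.is_connected(H):
                return k
    return n - 1


def all_minimum_cuts(G: nx.Graph) -> list[set]:
    k = brute_connectivity(G)
    cuts = []
    for cut in itertools.combinations(list(G.nodes), k):
        H = G.copy()
        H.remove_nodes_from(cut)
        if H.number_of_nodes() and not nx.is_connected(H):
            cuts.append(set(cut))
    return cuts


def bruteforce_cohesive_block_sets(G: nx.Graph) -> set[tuple[frozenset, int]]:
    """All (node set, connectivity) blocks via exploration of every minimum cut,
    pruned like the package output (a block contained in another with equal or
    higher cohesion is dropped; component roots always kept)."""
    cands: list[tuple[frozenset, int]] = []
    roots = []
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        k = brute_connectivity(sub)
        roots.append(frozenset(comp))
        cands.append((frozenset(comp), k))
        _recurse(sub, k, cands, set())
    uniq: dict[frozenset, int] = {}
    for nodes, k in cands:
        uniq[nodes] = max(k, uniq.get(nodes, 0))
    kept = set()
    for nodes, k in uniq.items():
        absorbed = any(
            nodes < other and k <= ok for other, ok in uniq.items() if other != nodes
        )
        if absorbed and nodes not in roots:
            continue
        kept.add((nodes, k))
    return kept


def _recurse(sub, parent_k, cands, seen):
    n = sub.number_of_nodes()
    if n <= 2 or sub.number_of_edges() == n * (n - 1) // 2:
        return
    key = (frozenset(sub.nodes), parent_k)
    if key in seen:
        return
    seen.add(key)
    for cut in all_minimum_cuts(sub):
        rest = sub.subgraph(set(sub.nodes) - cut)
        for comp in nx.connected_components(rest):
            cand_nodes = set(comp) | cut
            if cand_nodes == set(sub.nodes):
                continue
            cand = sub.subgraph(cand_nodes)
            k = brute_connectivity(cand)
            if k > parent_k:
                cands.append((frozenset(cand_nodes), k))
                _recurse(cand, k, cands, seen)
            else:
                _recurse(cand, parent_k, cands, seen)


def basis_variance_closed_form(t: np.ndarray) -> np.ndarray:
    """Closed-form solve of ((D-2)I + J) w = rowsums(T) via the analytic
    inverse (aI + bJ)^-1 = (1/a)(I - b J / (a + b D))."""
    D = t.shape[0]
    b = t.sum(axis=1)
    a = D - 2
    inv = (np.eye(D) - np.ones((D, D)) / (a + D)) / a
    return inv @ b
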
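"""Independent reference implementations used to validate the ring engine.

Everything here is deliberately naive (exhaustive walks, networkx cycle
enumeration) and shares no code with ringorder's search.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from ringorder.hbonds import HBond, HBondGraph

ZERO = (0, 0, 0)


def graph_from_directed_edges(n: int, arcs) -> HBondGraph:
    """Build a synthetic (non-geometric) HBondGraph from (donor, acceptor) arcs."""
    edges = [
        HBond(donor=a, acceptor=b, hydrogen=0, image_shift=ZERO, oo_distance=2.8, ooh_angle=5.0)
        for a, b in arcs
    ]
    return HBondGraph(n, edges, np.array([100.0, 100.0, 100.0]))


def random_hbond_graph(seed: int, max_nodes: int = 14) -> HBondGraph:
    """Random directed graph with swept edge density, zero image shifts."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    # sweep the undirected edge density up to ~mean degree 4 (ice-like);
    # denser 14-node graphs carry millions of <=10-cycles and add nothing
    p = float(rng.uniform(0.02, 2.0 / n))
    arcs = []
    for a in range(n):
        for b in range(n):
            if a != b and rng.random() < p:
                arcs.append((a, b))
    return graph_from_directed_edges(n, arcs)


def canonical_cycle(seq) -> tuple:
    """Rotation- and reflection-invariant form of a vertex cycle."""
    seq = list(seq)
    best = None
    for s in (seq, seq[::-1]):
        k = s.index(min(s))
        rot = tuple(s[k:] + s[:k])
        if best is None or rot < best:
            best = rot
    return best


def nx_simple_cycles(graph: HBondGraph, max_ring: int = 10) -> set:
    """All undirected simple cycles of length 3..max_ring via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_waters))
    g.add_edges_from((hb.donor, hb.acceptor) for hb in graph.edges)
    out = set()
    for cyc in nx.simple_cycles(g, length_bound=max_ring):
        if len(cyc) >= 3:
            out.add(canonical_cycle(cyc))
    return out


def naive_closed_walk_instances(graph: HBondGraph, n: int) -> int:
    """Count raw traversal instances of length-n closed simple walks.

    Every starting vertex and both travel directions are counted separately,
    so an isolated n-ring yields 2n instances.
    """
    adj: dict[int, set[int]] = {v: set() for v in range(graph.n_waters)}
    for hb in graph.edges:
        adj[hb.donor].add(hb.acceptor)
        adj[hb.acceptor].add(hb.donor)
    count = 0

    def walk(start, v, depth, visited):
        nonlocal count
        for u in adj[v]:
            if u == start and depth == n:
                count += 1
            elif u not in visited and depth < n:
                walk(start, u, depth + 1, visited | {u})

    for s in range(graph.n_waters):
        walk(s, s, 1, {s})
    return count


def directional_by_bruteforce(graph: HBondGraph, members) -> bool:
    """A ring is directional iff its arcs can run head-to-tail one way round."""
    arcs = {(hb.donor, hb.acceptor) for hb in graph.edges}
    m = list(members)
    n = len(m)
    fwd = all((m[i], m[(i + 1) % n]) in arcs for i in range(n))
    bwd = all((m[(i + 1) % n], m[i]) in arcs for i in range(n))
    return fwd or bwd
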
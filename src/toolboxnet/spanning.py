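"""Linearization of reaction networks into spanning trees.

Both procedures root the tree at a designated metabolite (pyruvate, KEGG
C00022, for the real network) and cover every metabolite that can reach the
root along directed substrate->product edges.  The random-spanning-tree
walker grows branches as self-avoiding random walks that stop on first
contact with the existing tree, producing long critical-like branches; the
shortest-path variant attaches every metabolite by a geodesic, producing a
supercritical tree with logarithmically short branches.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .branching import LayeredTree
from .errors import ToolboxError

__all__ = ["random_spanning_tree", "shortest_path_tree", "DEFAULT_ROOT"]

DEFAULT_ROOT = "C00022"  # pyruvate


def _tree_from_parent_map(parent_of: dict, root, meta: dict) -> LayeredTree:
    """Index nodes in BFS (level) order and build a LayeredTree."""
    children: dict = {}
    for child, parent in parent_of.items():
        children.setdefault(parent, []).append(child)
    order = [root]
    depth_of = {root: 0}
    q = [root]
    while q:
        nxt = []
        for node in q:
            for ch in sorted(children.get(node, [])):
                depth_of[ch] = depth_of[node] + 1
                order.append(ch)
                nxt.append(ch)
        q = nxt
    index = {lab: i for i, lab in enumerate(order)}
    parents = np.array(
        [-1] + [index[parent_of[lab]] for lab in order[1:]], dtype=np.int64
    )
    depths = np.array([depth_of[lab] for lab in order], dtype=np.int64)
    tree = LayeredTree(parents, depths, labels=order, meta=meta)
    tree.validate()
    return tree


def _reaching_set(graph: nx.DiGraph, root) -> set:
    """Nodes with a directed path to the root (root excluded)."""
    return set(nx.ancestors(graph, root))


def random_spanning_tree(
    graph: nx.DiGraph,
    root,
    seed=None,
    *,
    max_restarts: int = 100,
):
    """Spanning tree via self-avoiding random walks toward the root.

    Repeatedly picks a uniformly random uncovered metabolite and walks along
    directed edges, avoiding its own path, until the walk first merges with
    the tree (or reaches the root); the walked path then becomes a tree
    branch.  A walk that dead-ends restarts from the same metabolite, at most
    ``max_restarts`` times, after which the metabolite is attached by its
    shortest path to the tree (recorded in the report).

    Returns ``(tree, report)`` where the report lists metabolites excluded
    because they cannot reach the root, and those attached by fallback.
    """
    if root not in graph:
        raise ToolboxError(f"root {root!r} not in graph")
    rng = np.random.default_rng(seed)
    reach = _reaching_set(graph, root)
    excluded = sorted(set(graph.nodes) - reach - {root})
    in_tree = {root}
    parent_of: dict = {}
    uncovered = sorted(reach)
    fallbacks = []
    succ = {n: sorted(graph.successors(n)) for n in graph.nodes}
    while uncovered:
        pick = int(rng.integers(len(uncovered)))
        start = uncovered[pick]
        if start in in_tree:
            uncovered[pick] = uncovered[-1]
            uncovered.pop()
            continue
        path = None
        for _ in range(max_restarts):
            trial = [start]
            on_path = {start}
            node = start
            while node not in in_tree:
                options = [v for v in succ[node] if v not in on_path]
                if not options:
                    trial = None
                    break
                node = options[int(rng.integers(len(options)))]
                trial.append(node)
                on_path.add(node)
            if trial is not None:
                path = trial
                break
        if path is None:
            # fall back to the shortest route into the current tree
            path = _shortest_path_to_tree(succ, start, in_tree)
            fallbacks.append(start)
        for child, parent in zip(path[:-1], path[1:]):
            if child not in in_tree:
                parent_of[child] = parent
                in_tree.add(child)
    meta = {"root": str(root), "mode": "random-walk", "n_excluded": len(excluded)}
    tree = _tree_from_parent_map(parent_of, root, meta)
    return tree, {"excluded": excluded, "fallback": sorted(fallbacks)}


def _shortest_path_to_tree(succ: dict, start, in_tree: set) -> list:
    prev = {start: None}
    q = [start]
    while q:
        nxt = []
        for node in q:
            for v in succ[node]:
                if v in prev:
                    continue
                prev[v] = node
                if v in in_tree:
                    path = [v]
                    while prev[path[-1]] is not None:
                        path.append(prev[path[-1]])
                    return list(reversed(path))  # start -> ... -> tree node
                nxt.append(v)
        q = nxt
    raise ToolboxError(f"{start!r} cannot reach the tree")


def shortest_path_tree(graph: nx.DiGraph, root, seed=None):
    """Breadth-first tree of shortest directed distances to the root.

    Levels are geodesic distances; when a metabolite has several neighbors
    one level closer to the root, its parent is chosen uniformly at random
    (seeded).  Returns ``(tree, report)`` with unreachable metabolites
    excluded and reported.
    """
    if root not in graph:
        raise ToolboxError(f"root {root!r} not in graph")
    rng = np.random.default_rng(seed)
    dist = {root: 0}
    q = [root]
    rev = {n: sorted(graph.predecessors(n)) for n in graph.nodes}
    order = []
    while q:
        nxt = []
        for node in q:
            for v in rev[node]:
                if v not in dist:
                    dist[v] = dist[node] + 1
                    order.append(v)
                    nxt.append(v)
        q = nxt
    excluded = sorted(set(graph.nodes) - set(dist))
    parent_of = {}
    succ = {n: sorted(graph.successors(n)) for n in graph.nodes}
    for node in order:
        options = [v for v in succ[node] if dist.get(v, -2) == dist[node] - 1]
        parent_of[node] = options[int(rng.integers(len(options)))]
    meta = {"root": str(root), "mode": "shortest-path", "n_excluded": len(excluded)}
    tree = _tree_from_parent_map(parent_of, root, meta)
    return tree, {"excluded": excluded}
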
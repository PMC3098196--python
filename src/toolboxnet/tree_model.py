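"""Toolbox pathway acquisition on a layered universal tree.

An organism repeatedly picks a random unacquired nutrient (leaf of the
universal tree) and acquires the linear pathway connecting it to its existing
network: the leaf plus all ancestors up to, but excluding, the first node it
already owns.  The number of pathways N_L (one dedicated transcriptional
regulator each) and of owned metabolites N_M are recorded after every step;
on critical universal trees N_L grows quadratically with N_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branching import LayeredTree
from .errors import LeavesExhaustedError
from .trajectory import Trajectory

__all__ = [
    "OrganismTreeState",
    "init_tree_state",
    "add_random_pathway",
    "simulate_full_trajectory",
    "acquire_leaf_fraction",
    "occupation_by_level",
]


@dataclass
class OrganismTreeState:
    """Acquired subtree of the universal tree.

    The acquired set is always a connected subtree containing the root;
    ``n_m`` is its size, ``n_l`` the number of acquisition events (equal to
    the number of acquired leaves).
    """

    acquired: np.ndarray  # bool per node
    n_l: int
    n_m: int
    _leaf_pool: np.ndarray  # unacquired leaves, first _pool_size entries live
    _pool_size: int

    @property
    def remaining_leaves(self) -> int:
        return self._pool_size


def init_tree_state(tree: LayeredTree) -> OrganismTreeState:
    leaves = tree.leaves.copy()
    return OrganismTreeState(
        acquired=np.zeros(tree.n_nodes, dtype=bool),
        n_l=0,
        n_m=0,
        _leaf_pool=leaves,
        _pool_size=leaves.size,
    )


def add_random_pathway(
    tree: LayeredTree, state: OrganismTreeState, rng: np.random.Generator
) -> OrganismTreeState:
    """Acquire one uniformly chosen unacquired leaf and its path to the net.

    The path is extended toward the root until it first intersects the
    acquired set (the whole root path on the first call).  Mutates and
    returns ``state``.
    """
    if state._pool_size == 0:
        raise LeavesExhaustedError("all leaves are already acquired")
    pick = int(rng.integers(state._pool_size))
    leaf = int(state._leaf_pool[pick])
    state._pool_size -= 1
    state._leaf_pool[pick] = state._leaf_pool[state._pool_size]
    parents = tree.parents
    acquired = state.acquired
    node = leaf
    added = 0
    while node != -1 and not acquired[node]:
        acquired[node] = True
        added += 1
        node = parents[node]
    state.n_l += 1
    state.n_m += added
    return state


def simulate_full_trajectory(tree: LayeredTree, seed=None) -> Trajectory:
    """Add leaves in uniform random order until exhaustion.

    The trajectory has one (N_L, N_M) point per acquisition; its endpoint is
    (L_tot, M_tot) regardless of the ordering.
    """
    rng = np.random.default_rng(seed)
    state = init_tree_state(tree)
    n_steps = state.remaining_leaves
    n_l = np.empty(n_steps, dtype=np.int64)
    n_m = np.empty(n_steps, dtype=np.int64)
    for k in range(n_steps):
        add_random_pathway(tree, state, rng)
        n_l[k] = state.n_l
        n_m[k] = state.n_m
    return Trajectory(n_l, n_m, meta={"seed": seed, "tree_nodes": tree.n_nodes})


def acquire_leaf_fraction(
    tree: LayeredTree, x: float, rng: np.random.Generator
) -> OrganismTreeState:
    """Acquire ``round(x * L_tot)`` random leaves (for occupation profiles)."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    state = init_tree_state(tree)
    for _ in range(int(round(x * state.remaining_leaves))):
        add_random_pathway(tree, state, rng)
    return state


def occupation_by_level(tree: LayeredTree, state: OrganismTreeState) -> np.ndarray:
    """Number of acquired nodes per level (the simulation's m_d)."""
    return np.bincount(
        tree.depths[state.acquired], minlength=tree.depth + 1
    ).astype(np.int64)
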
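"""Galton-Watson universal trees and the mean-field layer-occupation theory.

The universal metabolic network is modelled as a rooted directed tree whose
root is the metabolic core.  Layers are indexed by the distance ``d`` from the
root; a node at level ``d`` has 0, 1 or 2 children at level ``d+1`` with
probabilities ``p0``, ``p1``, ``p2``.  The mean offspring number
``Lambda = p1 + 2*p2`` distinguishes critical (``Lambda == 1``, equivalently
``p0 == p2``) from supercritical (``Lambda > 1``) universes.  Leaves of the
tree are nutrients; paths from leaves to the root are metabolic pathways.

The mean-field theory tracks the expected per-layer occupation of an
organism-specific subtree that has acquired a fraction ``x`` of all leaves,
via the downward recursion

    m_d = x*Lambda_d + m_{d+1} - B_d * (m_{d+1} / M_{d+1})**2

whose bulk fixed point on a critical universe is ``p = sqrt(x)``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import BudgetExceededError, SamplingFailureError

__all__ = [
    "BranchingParams",
    "LayeredTree",
    "LayerStats",
    "TheoryProfile",
    "sample_tree",
    "layer_stats",
    "criticality_profile",
    "algebraic_growth_curve",
    "expected_layer_stats",
    "mean_field_iterate",
    "steady_state_fraction",
    "write_tree",
    "read_tree",
]


@dataclass(frozen=True)
class BranchingParams:
    """Offspring law of the two-child Galton-Watson process.

    ``p0``, ``p1``, ``p2`` are the probabilities for a node to have 0, 1 or 2
    children at the next layer.  The process is critical exactly when
    ``p0 == p2``.
    """

    p0: float
    p1: float
    p2: float

    def __post_init__(self):
        probs = (self.p0, self.p1, self.p2)
        if any(p < 0 for p in probs):
            raise ValueError(f"offspring probabilities must be >= 0, got {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"offspring probabilities must sum to 1, got {probs}")

    @property
    def mean_offspring(self) -> float:
        return self.p1 + 2.0 * self.p2

    @property
    def is_critical(self) -> bool:
        return abs(self.p0 - self.p2) < 1e-12

    @property
    def is_supercritical(self) -> bool:
        return self.p2 - self.p0 > 1e-12


class LayerStats(NamedTuple):
    """Per-level counts of a universal tree.

    M: total nodes per level; L: leaves (0 children); B: branching excess
    ``sum(max(children - 1, 0))`` per level, which equals the number of
    two-child branch points for binary trees and makes the conservation
    identity ``M[d+1] = M[d] - L[d] + B[d]`` exact for any tree.
    """

    M: np.ndarray
    L: np.ndarray
    B: np.ndarray


@dataclass
class LayeredTree:
    """Rooted tree stored as parent pointers, nodes ordered by level.

    ``parents[i]`` is the index of node ``i``'s parent (-1 for the root),
    ``depths[i]`` its distance from the root.  ``labels`` optionally carries
    metabolite identifiers (used by linearized reaction-network trees).
    """

    parents: np.ndarray
    depths: np.ndarray
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.parents.size

    @property
    def depth(self) -> int:
        return int(self.depths.max(initial=0))

    @property
    def child_counts(self) -> np.ndarray:
        return np.bincount(self.parents[self.parents >= 0], minlength=self.n_nodes)

    @property
    def leaves(self) -> np.ndarray:
        """Indices of nodes with no children."""
        return np.flatnonzero(self.child_counts == 0)

    @property
    def n_leaves(self) -> int:
        return int(self.leaves.size)

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise ValueError("empty tree")
        if int((self.parents == -1).sum()) != 1 or self.parents[0] != -1:
            raise ValueError("tree must have exactly one root at index 0")
        if self.depths[0] != 0:
            raise ValueError("root must be at depth 0")
        nonroot = np.flatnonzero(self.parents >= 0)
        if nonroot.size and not np.all(
            self.depths[nonroot] == self.depths[self.parents[nonroot]] + 1
        ):
            raise ValueError("child depth must be parent depth + 1")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels length mismatch")


def layer_stats(tree: LayeredTree) -> LayerStats:
    """Per-level totals, leaf counts and branching excess of a tree."""
    depth = tree.depth
    M = np.bincount(tree.depths, minlength=depth + 1)
    counts = tree.child_counts
    L = np.bincount(tree.depths[counts == 0], minlength=depth + 1)
    excess = np.maximum(counts - 1, 0)
    B = np.bincount(tree.depths, weights=excess, minlength=depth + 1).astype(np.int64)
    return LayerStats(M=M, L=L, B=B)


def _grow(params: BranchingParams, depth, size_cap, rng) -> LayeredTree | None:
    """One Galton-Watson realization; None if the size cap was exceeded."""
    parents = [-1]
    depths = [0]
    frontier = np.array([0], dtype=np.int64)
    d = 0
    probs = [params.p0, params.p1, params.p2]
    while frontier.size and (depth is None or d < depth):
        n_children = rng.choice(3, size=frontier.size, p=probs)
        total = int(n_children.sum())
        if total:
            new_parents = np.repeat(frontier, n_children)
            if len(parents) + total > size_cap:
                return None
            parents.extend(new_parents.tolist())
            depths.extend([d + 1] * total)
            start = len(parents) - total
            frontier = np.arange(start, len(parents), dtype=np.int64)
        else:
            frontier = np.empty(0, dtype=np.int64)
        d += 1
    return LayeredTree(np.array(parents), np.array(depths))


def sample_tree(
    params: BranchingParams,
    *,
    depth: int | None = None,
    size: int | None = None,
    tol: float = 0.1,
    seed=None,
    max_attempts: int = 100_000,
    node_budget: int = 1_000_000,
) -> LayeredTree:
    """Sample a Galton-Watson tree.

    Modes (combinable):

    - ``depth=D``: terminate the process at layer ``D`` (mandatory for
      supercritical parameters, whose unconstrained process never stops).
    - ``size=target``: rejection-sample until the total node count falls in
      ``[target*(1-tol), target*(1+tol)]``.

    Raises :class:`BudgetExceededError` if a single realization outgrows
    ``node_budget``, and :class:`SamplingFailureError` if the size window is
    not hit within ``max_attempts`` rejections.
    """
    rng = np.random.default_rng(seed)
    if size is not None and size < 1:
        raise ValueError("size target must be >= 1")
    cap = node_budget if size is None else min(node_budget, int(np.ceil(size * (1 + tol))))
    lo = 0 if size is None else int(np.ceil(size * (1 - tol)))
    for attempt in range(max_attempts if size is not None else 1):
        tree = _grow(params, depth, cap, rng)
        if tree is None:
            if size is None:
                raise BudgetExceededError(
                    f"tree exceeded node budget of {node_budget} nodes "
                    f"(params {params}, depth {depth})"
                )
            continue  # overshoot counts as a rejection
        if size is None or lo <= tree.n_nodes:
            tree.meta.update(
                p0=params.p0, p1=params.p1, p2=params.p2, attempts=attempt + 1
            )
            return tree
    raise SamplingFailureError(
        f"no tree of size {size}+-{tol:.0%} found in {max_attempts} attempts"
    )


def criticality_profile(M) -> np.ndarray:
    """Consecutive-layer ratios ``mu_d = M[d+1] / M[d]``.

    Supercritical universes converge to ``Lambda > 1``; critical ones decay
    to 1 like ``1 + theta/d`` (see :func:`algebraic_growth_curve`).
    """
    M = np.asarray(M, dtype=float)
    if M.size < 2:
        raise ValueError("need at least two layers to form ratios")
    if np.any(M[:-1] <= 0) or np.any(M[1:] < 0):
        raise ValueError("layer sizes must be positive")
    return M[1:] / M[:-1]


def algebraic_growth_curve(d, theta: float = 1.0) -> np.ndarray:
    """Reference ratio profile ``1 + theta/d`` of algebraic layer growth.

    ``theta = 1`` corresponds to the critical branching process conditioned
    on survival, for which ``M_d`` grows linearly in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("layer index must be positive")
    return 1.0 + theta / d


def expected_layer_stats(params: BranchingParams, depth: int) -> LayerStats:
    """Ensemble-expected layer counts ``M_d = Lambda**d`` of the process.

    Leaves and branch points per level follow as ``p0*M_d`` and ``p2*M_d``.
    Used as the input of :func:`mean_field_iterate` in "theory" mode.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    d = np.arange(depth + 1)
    M = params.mean_offspring ** d
    return LayerStats(M=M, L=params.p0 * M, B=params.p2 * M)


@dataclass
class TheoryProfile:
    """Mean-field occupation profile of an organism-specific subtree.

    ``x`` is the acquired-leaf fraction ``N_L / L_tot``; ``m[d]`` the expected
    number of organism metabolites at level ``d``; ``p[d] = m[d]/M[d]`` the
    occupation fraction; ``lam[d] = x*L[d]`` the expected acquired leaves and
    ``b[d]`` the expected organism branch points per level.
    """

    x: float
    m: np.ndarray
    p: np.ndarray
    lam: np.ndarray
    b: np.ndarray

    @property
    def p_bulk(self) -> float:
        """Occupation furthest from the deep boundary (level 0)."""
        return float(self.p[0])


def mean_field_iterate(
    stats: LayerStats | LayeredTree | BranchingParams,
    x: float,
    depth: int | None = None,
) -> TheoryProfile:
    """Iterate the layer-occupation recursion from the deepest layer down.

    ``stats`` may be per-layer counts, a sampled tree, or branching
    parameters (then ``depth`` is required and ensemble-expected counts are
    used).  The boundary condition is ``m_D = x * L_D``; each step applies

        m_d = x*L_d + m_{d+1} - B_d * (m_{d+1}/M_{d+1})**2

    i.e. acquired leaves entering at level ``d`` plus the distinct downstream
    conversions of level-``d+1`` organism metabolites, merged pairwise at
    branch points.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"leaf fraction x must lie in [0, 1], got {x}")
    if isinstance(stats, BranchingParams):
        if depth is None:
            raise ValueError("depth is required with BranchingParams input")
        stats = expected_layer_stats(stats, depth)
    elif isinstance(stats, LayeredTree):
        stats = layer_stats(stats)
    M = np.asarray(stats.M, dtype=float)
    L = np.asarray(stats.L, dtype=float)
    B = np.asarray(stats.B, dtype=float)
    D = M.size - 1
    lam = x * L
    m = np.zeros(D + 1)
    m[D] = lam[D]
    b = np.zeros(D + 1)
    for d in range(D - 1, -1, -1):
        p_next = m[d + 1] / M[d + 1] if M[d + 1] > 0 else 0.0
        b[d] = B[d] * p_next**2
        m[d] = lam[d] + m[d + 1] - b[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(M > 0, m / np.where(M > 0, M, 1.0), 0.0)
    return TheoryProfile(x=x, m=m, p=np.clip(p, 0.0, 1.0), lam=lam, b=b)


def steady_state_fraction(params: BranchingParams, x: float) -> float:
    """Bulk fixed point ``p_inf`` of the occupation recursion.

    Solves ``p2*p**2 - (Lambda-1)*p = x*p0`` for the physical root.  On a
    critical universe this is ``sqrt(x)``; on a supercritical one the
    ``x -> 0+`` limit is the discontinuous onset ``1 - p0/p2``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"leaf fraction x must lie in [0, 1], got {x}")
    lam1 = params.mean_offspring - 1.0  # = p2 - p0
    if params.p2 == 0.0:
        # linear equation: p0 * p = x * p0  (pure-path case p0 == 0 -> p = x too)
        return x
    disc = lam1 * lam1 + 4.0 * params.p2 * params.p0 * x
    p = (lam1 + np.sqrt(disc)) / (2.0 * params.p2)
    assert -1e-12 <= p <= 1.0 + 1e-12, f"no physical root for {params}, x={x}"
    return float(min(max(p, 0.0), 1.0))


def write_tree(tree: LayeredTree, path_or_buf) -> None:
    """Serialize a tree as a TSV edge list ``child<TAB>parent[<TAB>label]``.

    A single ``# meta:`` JSON header line carries parameters and seed so that
    :func:`read_tree` round-trips exactly.
    """
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# meta: {json.dumps(tree.meta, sort_keys=True)}\n")
        has_labels = tree.labels is not None
        for i in range(tree.n_nodes):
            row = f"{i}\t{tree.parents[i]}"
            if has_labels:
                row += f"\t{tree.labels[i]}"
            fh.write(row + "\n")
    finally:
        if own:
            fh.close()


def read_tree(path_or_buf) -> LayeredTree:
    """Inverse of :func:`write_tree`."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        meta = {}
        parents, labels = [], []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# meta:"):
                    meta = json.loads(line[len("# meta:"):])
                continue
            parts = line.split("\t")
            parents.append(int(parts[1]))
            if len(parts) > 2:
                labels.append(parts[2])
    finally:
        if own:
            fh.close()
    parents = np.array(parents, dtype=np.int64)
    depths = np.zeros_like(parents)
    for i in range(1, parents.size):
        depths[i] = depths[parents[i]] + 1
    tree = LayeredTree(parents, depths, labels=labels or None, meta=meta)
    tree.validate()
    return tree


def tree_to_string(tree: LayeredTree) -> str:
    buf = io.StringIO()
    write_tree(tree, buf)
    return buf.getvalue()
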